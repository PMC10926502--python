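"""Duplex real-time PCR interpretation: calls, delta-Cq, standard curves.

A sample runs in two channels — a diagnostic hydrolysis probe and an
internal-control probe.  A channel is *amplified-positive* when its end RFU
reaches the channel threshold and its Cq lies inside the positive window.
The four-way call:

- ``positive``: both channels amplified-positive and |dCq| within the cutoff;
- ``anomalous``: diagnostic Cq below the window while control Cq is above it
  (the copy-number-imbalance pattern that prompts a singleplex rerun), both
  channels amplifying with |dCq| beyond the cutoff, or a diagnostic-positive
  sample whose control channel dropped out;
- ``negative``: control amplified-positive, diagnostic not (a non-target);
- ``failed``: neither channel amplified-positive (degraded DNA).

Default thresholds follow the validated assay: RFU 500 (diagnostic) / 250
(control), Cq window 5-30, dCq cutoff 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QpcrError


@dataclass
class QpcrWell:
    sample_id: str
    channel: str                 # "diagnostic" | "control"
    cq: float | None             # None = no amplification
    end_rfu: float

    def __post_init__(self) -> None:
        if self.channel not in ("diagnostic", "control"):
            raise QpcrError(f"unknown channel {self.channel!r}")
        if self.cq is not None and not self.cq > 0:
            raise QpcrError(f"Cq must be positive, got {self.cq}")
        if self.end_rfu < 0:
            raise QpcrError(f"end RFU must be >= 0, got {self.end_rfu}")


@dataclass
class CallThresholds:
    rfu_diag: float = 500.0
    rfu_ctrl: float = 250.0
    cq_min: float = 5.0
    cq_max: float = 30.0
    delta_max: float = 7.0

    def __post_init__(self) -> None:
        if not (0 < self.cq_min < self.cq_max):
            raise QpcrError("need 0 < cq_min < cq_max")
        if min(self.rfu_diag, self.rfu_ctrl, self.delta_max) <= 0:
            raise QpcrError("thresholds must be positive")

    def rfu_for(self, channel: str) -> float:
        return self.rfu_diag if channel == "diagnostic" else self.rfu_ctrl


@dataclass
class SampleCall:
    sample_id: str
    call: str                          # positive | negative | anomalous | failed
    delta_cq: float | None
    reasons: list[str] = field(default_factory=list)


def delta_cq(ctrl_cq: float | None, diag_cq: float | None) -> float:
    """|control Cq - diagnostic Cq|; both values must be present."""
    if ctrl_cq is None or diag_cq is None:
        raise QpcrError("delta_cq requires amplification in both channels")
    return abs(ctrl_cq - diag_cq)


def _amplified(well: QpcrWell, t: CallThresholds) -> bool:
    """Real signal: Cq present and end RFU at or above the channel threshold."""
    return well.cq is not None and well.end_rfu >= t.rfu_for(well.channel)


def _amplified_positive(well: QpcrWell, t: CallThresholds) -> bool:
    return _amplified(well, t) and t.cq_min <= well.cq <= t.cq_max


def classify_sample(diag: QpcrWell, ctrl: QpcrWell, t: CallThresholds | None = None) -> SampleCall:
    """Four-way call for one sample's diagnostic/control well pair."""
    t = t or CallThresholds()
    if diag.channel != "diagnostic" or ctrl.channel != "control":
        raise QpcrError("classify_sample needs one diagnostic and one control well")
    if diag.sample_id != ctrl.sample_id:
        raise QpcrError("wells belong to different samples")
    dcq = None
    if diag.cq is not None and ctrl.cq is not None:
        dcq = delta_cq(ctrl.cq, diag.cq)
    reasons: list[str] = []

    # anomalous patterns first: they describe wells that *did* produce signal
    # but in a configuration the duplex cannot interpret
    if (
        diag.cq is not None and ctrl.cq is not None
        and diag.cq < t.cq_min and ctrl.cq > t.cq_max
    ):
        reasons.append(
            f"diagnostic Cq {diag.cq:g} below window ({t.cq_min}) while control Cq "
            f"{ctrl.cq:g} above window ({t.cq_max}): copy-number imbalance pattern"
        )
        return SampleCall(diag.sample_id, "anomalous", dcq, reasons)
    d_ok = _amplified_positive(diag, t)
    c_ok = _amplified_positive(ctrl, t)
    if _amplified(diag, t) and _amplified(ctrl, t) and dcq is not None and dcq > t.delta_max:
        reasons.append(f"both channels amplified but dCq {dcq:.2f} > cutoff {t.delta_max:g}")
        return SampleCall(diag.sample_id, "anomalous", dcq, reasons)
    if d_ok and c_ok:
        reasons.append(
            f"both channels amplified-positive within Cq window and dCq {dcq:.2f} <= {t.delta_max:g}"
        )
        return SampleCall(diag.sample_id, "positive", dcq, reasons)
    if c_ok and not d_ok:
        reasons.append("control amplified-positive, diagnostic did not: non-target pattern")
        return SampleCall(diag.sample_id, "negative", dcq, reasons)
    if d_ok and not c_ok:
        reasons.append("diagnostic amplified-positive but control dropped out")
        return SampleCall(diag.sample_id, "anomalous", dcq, reasons)
    reasons.append("no amplified-positive channel: assay failure (degraded DNA?)")
    return SampleCall(diag.sample_id, "failed", dcq, reasons)


def classify_run(wells: list[QpcrWell], t: CallThresholds | None = None) -> list[SampleCall]:
    """Pair each sample's two channels and classify; errors on incomplete pairs."""
    by_sample: dict[str, dict[str, QpcrWell]] = {}
    for w in wells:
        slot = by_sample.setdefault(w.sample_id, {})
        if w.channel in slot:
            raise QpcrError(f"duplicate {w.channel} well for sample {w.sample_id!r}")
        slot[w.channel] = w
    calls = []
    for sid, slot in by_sample.items():
        if set(slot) != {"diagnostic", "control"}:
            raise QpcrError(f"sample {sid!r} lacks one channel of the duplex")
        calls.append(classify_sample(slot["diagnostic"], slot["control"], t))
    return calls


# --- standard curve ----------------------------------------------------------

@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r: float
    efficiency: float                 # E = 10^(-1/slope) - 1
    detection_floor: float | None     # lowest concentration with all replicates amplifying
    points: list[tuple[float, float | None]]


def fit_standard_curve(points: list[tuple[float, float | None]]) -> StandardCurve:
    """Least squares of Cq on log10(concentration) over amplifying replicates.

    ``points`` are (concentration ng/uL, Cq) pairs; Cq None marks a replicate
    that did not amplify (excluded from the fit, counted against the
    detection floor).  Requires >= 3 distinct amplifying concentrations.
    """
    for conc, _ in points:
        if conc <= 0:
            raise QpcrError(f"nonpositive concentration {conc}")
    fit_pts = [(c, q) for c, q in points if q is not None]
    concs = sorted({c for c, _ in fit_pts})
    if len(concs) < 3:
        raise QpcrError("need at least 3 distinct amplifying concentrations")
    x = np.log10([c for c, _ in fit_pts])
    y = np.array([q for _, q in fit_pts], dtype=float)
    res = stats.linregress(x, y)
    eff = 10.0 ** (-1.0 / res.slope) - 1.0 if res.slope != 0 else math.inf
    floor = None
    for conc in sorted({c for c, _ in points}, reverse=True):
        reps = [q for c, q in points if c == conc]
        if all(q is not None for q in reps):
            floor = conc
        else:
            break
    return StandardCurve(
        slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue),
        efficiency=float(eff), detection_floor=floor, points=list(points),
    )


# --- run summary -------------------------------------------------------------

def _stats(values: list[float]) -> dict:
    if not values:
        return {"n": 0, "min": None, "max": None, "mean": None, "sd": None, "sd_flag": ""}
    arr = np.asarray(values, dtype=float)
    if len(arr) == 1:
        return {
            "n": 1, "min": float(arr[0]), "max": float(arr[0]),
            "mean": float(arr[0]), "sd": 0.0, "sd_flag": "single_observation",
        }
    return {
        "n": len(arr), "min": float(arr.min()), "max": float(arr.max()),
        "mean": float(arr.mean()), "sd": float(arr.std(ddof=1)), "sd_flag": "",
    }


def summarize_run(calls: list[SampleCall], wells: list[QpcrWell], t: CallThresholds | None = None) -> dict:
    """Per-channel Cq/RFU statistics over amplified wells, call tally, and a
    suggested RFU threshold per channel (half the 5th percentile of amplified
    end-RFU, rounded to the nearest 50 — a conservative floor well below the
    observed signal cloud)."""
    if not wells:
        raise QpcrError("summarize_run needs at least one well")
    t = t or CallThresholds()
    out: dict = {"channels": {}, "calls": {}}
    for channel in ("diagnostic", "control"):
        chan_wells = [w for w in wells if w.channel == channel]
        amped = [w for w in chan_wells if w.cq is not None]
        cqs = [w.cq for w in amped]
        rfus = [w.end_rfu for w in amped]
        suggested = None
        if rfus:
            suggested = round(0.5 * float(np.percentile(rfus, 5)) / 50.0) * 50.0
        out["channels"][channel] = {
            "n_wells": len(chan_wells),
            "n_amplified": len(amped),
            "cq": _stats(cqs),
            "end_rfu": _stats(rfus),
            "suggested_rfu_threshold": suggested,
        }
    tally: dict[str, int] = {}
    for c in calls:
        tally[c.call] = tally.get(c.call, 0) + 1
    out["calls"] = tally
    return out


# --- I/O ---------------------------------------------------------------------

def read_well_table(path) -> list[QpcrWell]:
    """CSV with columns sample_id, channel, cq, end_rfu; empty cq = no amplification."""
    df = pd.read_csv(path, dtype={"sample_id": str, "channel": str})
    required = {"sample_id", "channel", "cq", "end_rfu"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrError(f"well table missing columns: {sorted(missing)}")
    wells = []
    for _, row in df.iterrows():
        cq = row["cq"]
        cq = None if pd.isna(cq) else float(cq)
        wells.append(QpcrWell(row["sample_id"], row["channel"].strip().lower(), cq, float(row["end_rfu"])))
    return wells


def write_call_report(calls: list[SampleCall], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "call": c.call,
                "delta_cq": c.delta_cq,
                "reasons": "; ".join(c.reasons),
            }
            for c in calls
        ]
    ).to_csv(path, index=False)
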