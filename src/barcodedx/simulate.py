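"""Seeded synthetic data: planted-haplotype barcode alignments and qPCR runs.

The barcode generator plants a known genealogy with no homoplasy: every
mutation strikes a previously untouched column, and every branch descends
from a *sampled* haplotype, so pairwise Hamming distances equal the summed
step counts along the connecting path and the statistical-parsimony network
of the data is exactly the planted tree.  The default configuration encodes
the structure the downstream analyses expect to recover:

- a large near-homogeneous main haplogroup: one center haplotype plus 12
  one-step and 1 two-step satellites (14 variable positions in total, group
  diameter 3);
- an outlier lineage of two identical samples 20 steps from the center;
- three nontarget pseudo-species on a nested chain at 40/45/60 steps from
  the center (so the 40 chain-stem mutations are fixed target/nontarget
  differences);
- one outgroup sample 80 steps from the center.

Nontarget-lineage mutations are preferentially placed inside a "divergent
tract", emulating the locally SNV-dense regions that make window scanning
worthwhile on real barcodes; main-group and outlier mutations fall uniformly.
Subspecies labels are assigned round-robin across main-group members,
deliberately independent of haplotype identity.

The qPCR generator draws wells per truth class from the validated assay's
observed distributions, truncated/floored so that each class satisfies its
defining call rule by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, SampleRecord, SampleTable
from .qpcr import CallThresholds, QpcrWell

BASES = np.array(list("ACGT"))


@dataclass
class BarcodeSimConfig:
    L: int = 420
    center_members: int = 60
    #: (steps from center, member count) per main-group satellite haplotype
    satellites: tuple = (
        (1, 4), (1, 3), (1, 2), (1, 2), (1, 1), (1, 1),
        (1, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1),
        (2, 2),
    )
    outlier_steps: int = 20
    outlier_members: int = 2
    #: extra steps of each nontarget pseudo-species beyond its chain parent
    #: (chain: center -> ntA -> ntB -> ntC), giving center distances 40/45/60
    nontarget_chain_steps: tuple = (40, 5, 15)
    nontarget_members: tuple = (2, 2, 2)
    outgroup_steps: int = 80
    subspecies_names: tuple = ("howardi", "tenella", "duodecimnotata", "undecimpunctata")
    #: interval of columns receiving most inter-lineage mutations (SNV-dense tract)
    divergent_tract: tuple = (140, 270)
    tract_fraction: float = 0.65

    @property
    def main_variable_positions(self) -> int:
        return sum(s for s, _ in self.satellites)

    @property
    def main_diameter(self) -> int:
        steps = sorted((s for s, _ in self.satellites), reverse=True)
        if not steps:
            return 0
        return steps[0] + (steps[1] if len(steps) > 1 else 0)

    def total_steps(self) -> int:
        return (
            self.main_variable_positions
            + self.outlier_steps
            + sum(self.nontarget_chain_steps)
            + self.outgroup_steps
        )


def _draw_positions(rng, k: int, available: set, tract: set, frac: float | None) -> list[int]:
    """k unused columns; ``frac`` share from the divergent tract, None = uniform."""
    if frac is None:
        pool = sorted(available)
        chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        available.difference_update(chosen)
        return chosen
    in_tract = sorted(available & tract)
    out_tract = sorted(available - tract)
    k_in = min(int(round(frac * k)), len(in_tract))
    k_out = k - k_in
    if k_out > len(out_tract):
        k_in = min(k - len(out_tract), len(in_tract))
        k_out = k - k_in
    chosen = []
    if k_in:
        chosen += [in_tract[i] for i in rng.choice(len(in_tract), size=k_in, replace=False)]
    if k_out:
        chosen += [out_tract[i] for i in rng.choice(len(out_tract), size=k_out, replace=False)]
    available.difference_update(chosen)
    return chosen


def _mutate(rng, seq: np.ndarray, positions: list[int]) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        alternatives = [b for b in range(4) if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return out


def generate_barcode_dataset(
    cfg: BarcodeSimConfig | None = None, seed: int = 0
) -> tuple[Alignment, SampleTable, dict]:
    """Planted barcode alignment + metadata + ground-truth summary.

    Same seed, same config -> byte-identical output.  The truth dict records
    the planted statistics (main-group variable positions, diameter, outlier
    step count) and a per-sample lineage map.
    """
    cfg = cfg or BarcodeSimConfig()
    if cfg.total_steps() > cfg.L:
        raise ValueError(
            f"planted mutations ({cfg.total_steps()}) exceed sequence length {cfg.L}"
        )
    rng = np.random.default_rng(seed)
    center = rng.integers(0, 4, size=cfg.L)
    available = set(range(cfg.L))
    tract = set(range(*cfg.divergent_tract))

    ids: list[str] = []
    rows: list[str] = []
    records: list[SampleRecord] = []
    lineage: dict[str, str] = {}

    def add_samples(prefix: str, seq: np.ndarray, count: int, species: str, group: str,
                    locality: str, lin: str) -> list[str]:
        text = "".join(BASES[seq])
        new = []
        for k in range(count):
            sid = f"{prefix}{k + 1:02d}"
            ids.append(sid)
            rows.append(text)
            records.append(SampleRecord(sid, species, group, "", locality, "simulated"))
            lineage[sid] = lin
            new.append(sid)
        return new

    main_ids = add_samples("und_c", center, cfg.center_members,
                           "Diabrotica undecimpunctata", "target", "core range", "main")
    for si, (steps, members) in enumerate(cfg.satellites, start=1):
        pos = _draw_positions(rng, steps, available, tract, frac=None)
        seq = _mutate(rng, center, pos)
        main_ids += add_samples(f"und_s{si:02d}_", seq, members,
                                "Diabrotica undecimpunctata", "target", "core range", "main")
    pos = _draw_positions(rng, cfg.outlier_steps, available, tract, frac=None)
    outlier = _mutate(rng, center, pos)
    add_samples("und_wca", outlier, cfg.outlier_members,
                "Diabrotica undecimpunctata", "target", "western California", "outlier")
    parent = center
    nt_names = ("Diabrotica sim_a", "Diabrotica sim_b", "Diabrotica sim_c")
    for name, steps, members in zip(nt_names, cfg.nontarget_chain_steps, cfg.nontarget_members):
        pos = _draw_positions(rng, steps, available, tract, frac=cfg.tract_fraction)
        parent = _mutate(rng, parent, pos)
        tag = name.split("_")[-1]
        add_samples(f"nt_{tag}", parent, members, name, "nontarget", "congener range", f"nt_{tag}")
    pos = _draw_positions(rng, cfg.outgroup_steps, available, tract, frac=None)
    outgroup = _mutate(rng, center, pos)
    add_samples("outg", outgroup, 1, "Trichobrotica sim", "outgroup", "outgroup", "outgroup")

    # subspecies labels round-robin over main-group members, independent of haplotype
    for i, sid in enumerate(main_ids):
        rec = next(r for r in records if r.sample_id == sid)
        rec.subspecies = cfg.subspecies_names[i % len(cfg.subspecies_names)]

    aln = Alignment(ids, rows)
    table = SampleTable.from_records(records)
    truth = {
        "lineage": lineage,
        "main_variable_positions": cfg.main_variable_positions,
        "main_diameter": cfg.main_diameter,
        "outlier_steps": cfg.outlier_steps,
        "nontarget_center_distances": tuple(
            np.cumsum(cfg.nontarget_chain_steps).tolist()
        ),
        "main_sample_ids": list(main_ids),
    }
    return aln, table, truth


@dataclass
class ControlSimConfig:
    """18S-like control locus: variable positions confined to the flanks."""

    L: int = 300
    conserved_core: tuple = (80, 220)
    flank_variants_per_lineage: int = 3


def generate_control_dataset(
    table: SampleTable, cfg: ControlSimConfig | None = None, seed: int = 0
) -> Alignment:
    """A conserved-locus alignment over the same samples (control-assay design).

    Each species gets a few private variants in the flanking regions; the core
    block is invariant across every sample, as in a ribosomal control locus.
    """
    cfg = cfg or ControlSimConfig()
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=cfg.L)
    flanks = [j for j in range(cfg.L) if not (cfg.conserved_core[0] <= j < cfg.conserved_core[1])]
    available = set(flanks)
    species = []
    for rec in table.records.values():
        if rec.species not in species:
            species.append(rec.species)
    seq_by_species = {}
    for sp in species:
        k = min(cfg.flank_variants_per_lineage, len(available))
        pos = [sorted(available)[i] for i in rng.choice(len(available), size=k, replace=False)]
        available.difference_update(pos)
        seq_by_species[sp] = _mutate(rng, base, pos)
    ids, rows = [], []
    for rec in table.records.values():
        ids.append(rec.sample_id)
        rows.append("".join(BASES[seq_by_species[rec.species]]))
    return Alignment(ids, rows)


# --- qPCR run simulation -----------------------------------------------------

@dataclass
class QpcrSimConfig:
    n_positive: int = 106
    n_anomalous: int = 4
    n_negative: int = 5
    n_failed: int = 1
    diag_cq_mean: float = 15.71
    diag_cq_sd: float = 4.38
    delta_cq_mean: float = 1.50
    delta_cq_sd: float = 0.65
    diag_rfu_mean: float = 1359.33
    diag_rfu_sd: float = 209.07
    ctrl_rfu_mean: float = 1533.68
    ctrl_rfu_sd: float = 546.79
    anomalous_diag_cq: tuple = (1.6, 4.95)
    anomalous_ctrl_cq: tuple = (32.9, 37.1)
    background_rfu_max: float = 200.0
    thresholds: CallThresholds = field(default_factory=CallThresholds)


def _truncnorm(rng, mean, sd, lo, hi):
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def generate_qpcr_run(
    cfg: QpcrSimConfig | None = None, seed: int = 0
) -> tuple[list[QpcrWell], pd.DataFrame]:
    """Wells per truth class, each satisfying its defining call rule by construction."""
    cfg = cfg or QpcrSimConfig()
    rng = np.random.default_rng(seed)
    t = cfg.thresholds
    wells: list[QpcrWell] = []
    labels = []
    counter = 0

    def add(sid, diag_cq, diag_rfu, ctrl_cq, ctrl_rfu, label):
        wells.append(QpcrWell(sid, "diagnostic", diag_cq, diag_rfu))
        wells.append(QpcrWell(sid, "control", ctrl_cq, ctrl_rfu))
        labels.append({"sample_id": sid, "truth": label})

    for _ in range(cfg.n_positive):
        counter += 1
        sid = f"S{counter:04d}"
        dcq = _truncnorm(rng, cfg.diag_cq_mean, cfg.diag_cq_sd, t.cq_min, t.cq_max)
        mag = min(abs(rng.normal(cfg.delta_cq_mean, cfg.delta_cq_sd)), t.delta_max - 0.05)
        ccq = dcq + mag if rng.random() < 0.5 else dcq - mag
        ccq = min(max(ccq, t.cq_min), t.cq_max)
        drfu = max(rng.normal(cfg.diag_rfu_mean, cfg.diag_rfu_sd), t.rfu_diag + 1.0)
        crfu = max(rng.normal(cfg.ctrl_rfu_mean, cfg.ctrl_rfu_sd), t.rfu_ctrl + 1.0)
        add(sid, dcq, drfu, ccq, crfu, "positive")
    for _ in range(cfg.n_anomalous):
        counter += 1
        sid = f"S{counter:04d}"
        dcq = float(rng.uniform(*cfg.anomalous_diag_cq))
        ccq = float(rng.uniform(*cfg.anomalous_ctrl_cq))
        drfu = max(rng.normal(cfg.diag_rfu_mean, cfg.diag_rfu_sd), t.rfu_diag + 1.0)
        crfu = max(rng.normal(cfg.ctrl_rfu_mean, cfg.ctrl_rfu_sd), 0.0)
        add(sid, dcq, drfu, ccq, crfu, "anomalous")
    for _ in range(cfg.n_negative):
        counter += 1
        sid = f"S{counter:04d}"
        ccq = _truncnorm(rng, 17.18, 3.99, t.cq_min, t.cq_max)
        crfu = max(rng.normal(cfg.ctrl_rfu_mean, cfg.ctrl_rfu_sd), t.rfu_ctrl + 1.0)
        add(sid, None, float(rng.uniform(0, cfg.background_rfu_max)), ccq, crfu, "negative")
    for _ in range(cfg.n_failed):
        counter += 1
        sid = f"S{counter:04d}"
        add(
            sid,
            None, float(rng.uniform(0, cfg.background_rfu_max)),
            None, float(rng.uniform(0, cfg.background_rfu_max)),
            "failed",
        )
    return wells, pd.DataFrame(labels, columns=["sample_id", "truth"])


def wells_to_frame(wells: list[QpcrWell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample_id": w.sample_id, "channel": w.channel, "cq": w.cq, "end_rfu": w.end_rfu}
            for w in wells
        ]
    )


@dataclass
class DilutionSimConfig:
    """Ten-fold serial dilution responding linearly in Cq (near-100% efficiency)."""

    concentrations: tuple = (100.0, 10.0, 1.0, 0.1, 0.01, 0.001, 0.0001)
    replicates: int = 4
    slope: float = -3.3219280948873623     # -1/log10(2): perfect doubling
    intercept: float = 18.7
    noise_sd: float = 0.15
    detection_floor: float = 0.1
    dropout_below_floor: float = 0.5       # per-replicate amplification failure rate


def generate_dilution_series(
    cfg: DilutionSimConfig | None = None, seed: int = 0
) -> list[tuple[float, float | None]]:
    cfg = cfg or DilutionSimConfig()
    rng = np.random.default_rng(seed)
    points: list[tuple[float, float | None]] = []
    for conc in cfg.concentrations:
        for _ in range(cfg.replicates):
            if conc < cfg.detection_floor and rng.random() < cfg.dropout_below_floor:
                points.append((conc, None))
                continue
            cq = cfg.intercept + cfg.slope * np.log10(conc) + rng.normal(0.0, cfg.noise_sd)
            points.append((conc, float(cq)))
    return points
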