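"""Aligned barcode matrices, sample metadata, and site-level reports.

This module holds the substrate the rest of the pipeline operates on: an
aligned multi-FASTA of IUPAC nucleotide sequences plus a sample table that
labels every sequence as ``target``, ``nontarget`` or ``outgroup``.  It
provides alignment trimming to an overlapping core, haplotype collapsing by
exact sequence identity, plurality/IUPAC consensus calling, and a per-column
classification of diagnostic sites (fixed differences, autapomorphies,
shared-ancestral states).

Coordinates are 0-based half-open internally; every user-facing report is
1-based, matching the convention of the barcoding literature ("position 326").
"""

from __future__ import annotations

import io
from collections import Counter, OrderedDict
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, MetadataError

IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")

#: IUPAC code -> set of bases it covers
IUPAC_TO_BASES = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_BASES.items()}

VALID_GROUPS = ("target", "nontarget", "outgroup")


@dataclass
class Alignment:
    """An aligned nucleotide matrix: equal-length rows over the IUPAC+gap alphabet."""

    sample_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.rows):
            raise AlignmentError("sample_ids and rows differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = [s for s, c in Counter(self.sample_ids).items() if c > 1]
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        L = len(self.rows[0])
        for sid, row in zip(self.sample_ids, self.rows):
            if len(row) != L:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length {len(row)}, expected {L}"
                )
            for pos, ch in enumerate(row):
                if ch not in IUPAC_CHARS:
                    raise AlignmentError(
                        f"illegal character {ch!r} in sequence {sid!r} at position {pos + 1}"
                    )

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    def row(self, sample_id: str) -> str:
        return self.rows[self.sample_ids.index(sample_id)]

    def subset(self, ids: list[str]) -> "Alignment":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in idx]
        if missing:
            raise AlignmentError(f"samples not in alignment: {missing}")
        return Alignment(list(ids), [self.rows[idx[s]] for s in ids])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; ids are headers up to the first whitespace."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path) -> None:
    recs = [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.sample_ids, aln.rows)]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def alignment_to_fasta(aln: Alignment) -> str:
    buf = io.StringIO()
    recs = [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.sample_ids, aln.rows)]
    SeqIO.write(recs, buf, "fasta")
    return buf.getvalue()


@dataclass
class SampleRecord:
    sample_id: str
    species: str
    group: str
    subspecies: str = ""
    locality: str = ""
    source: str = ""


@dataclass
class SampleTable:
    """One labeled record per aligned sample; groups are target/nontarget/outgroup."""

    records: "OrderedDict[str, SampleRecord]"

    @classmethod
    def from_records(cls, records: list[SampleRecord]) -> "SampleTable":
        out: OrderedDict[str, SampleRecord] = OrderedDict()
        for r in records:
            if r.sample_id in out:
                raise MetadataError(f"duplicate sample_id {r.sample_id!r}")
            g = r.group.strip().lower()
            if g not in VALID_GROUPS:
                raise MetadataError(
                    f"unknown group {r.group!r} for sample {r.sample_id!r}; "
                    f"expected one of {VALID_GROUPS}"
                )
            r.group = g
            out[r.sample_id] = r
        return cls(out)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.records

    def group_of(self, sample_id: str) -> str:
        try:
            return self.records[sample_id].group
        except KeyError:
            raise MetadataError(f"sample {sample_id!r} not in metadata table") from None

    def ids_in_group(self, group: str) -> list[str]:
        return [s for s, r in self.records.items() if r.group == group]

    def label_of(self, sample_id: str, field_name: str) -> str:
        return getattr(self.records[sample_id], field_name)

    def validate_against(self, aln: Alignment) -> None:
        missing = [s for s in aln.sample_ids if s not in self.records]
        if missing:
            raise MetadataError(f"aligned samples missing from metadata: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(r) for r in self.records.values()],
            columns=["sample_id", "species", "subspecies", "group", "locality", "source"],
        )


REQUIRED_METADATA_COLUMNS = ("sample_id", "species", "group")
OPTIONAL_METADATA_COLUMNS = ("subspecies", "locality", "source")


def read_metadata(path) -> SampleTable:
    """Read a tab-separated sample table (sample_id, species, subspecies, group, locality, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata table missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                species=row["species"],
                subspecies=row.get("subspecies", ""),
                group=row["group"],
                locality=row.get("locality", ""),
                source=row.get("source", ""),
            )
        )
    return SampleTable.from_records(records)


def write_metadata(table: SampleTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class TrimReport:
    removed_columns: list[int]   # 1-based positions of dropped columns
    removed_samples: list[str]


def trim_to_core(
    aln: Alignment,
    min_nongap_fraction: float = 0.7,
    min_span_fraction: float = 0.8,
) -> tuple[Alignment, TrimReport]:
    """Trim to an overlapping core: drop gappy columns, then short-spanning rows.

    Each pass removes columns whose non-gap fraction falls below
    ``min_nongap_fraction`` and then drops sequences covering fewer than
    ``min_span_fraction`` of the surviving columns.  Because dropping rows can
    re-expose gappy columns, passes repeat until nothing changes, so the
    operation is idempotent.  Reported removed-column positions are 1-based in
    the *input* coordinate system.
    """
    if not (0 < min_nongap_fraction <= 1 and 0 < min_span_fraction <= 1):
        raise ValueError("trim fractions must lie in (0, 1]")
    col_map = list(range(aln.L))        # surviving column -> input position
    ids, rows = list(aln.sample_ids), list(aln.rows)
    removed_cols: list[int] = []
    dropped: list[str] = []
    while True:
        n = len(rows)
        keep_cols, gone = [], []
        for j in range(len(col_map)):
            nongap = sum(1 for row in rows if row[j] != "-")
            if nongap > 0 and nongap / n >= min_nongap_fraction:
                keep_cols.append(j)
            else:
                gone.append(j)
        removed_cols.extend(col_map[j] + 1 for j in gone)
        if not keep_cols:
            raise AlignmentError("trimming removed every column")
        col_map = [col_map[j] for j in keep_cols]
        rows = ["".join(row[j] for j in keep_cols) for row in rows]
        m = len(keep_cols)
        keep_idx = []
        for i, row in enumerate(rows):
            span = sum(1 for ch in row if ch != "-")
            if span / m >= min_span_fraction:
                keep_idx.append(i)
            else:
                dropped.append(ids[i])
        if not keep_idx:
            raise AlignmentError("trimming removed every sequence")
        changed = len(gone) > 0 or len(keep_idx) < len(rows)
        ids = [ids[i] for i in keep_idx]
        rows = [rows[i] for i in keep_idx]
        if not changed:
            break
    return Alignment(ids, rows), TrimReport(sorted(removed_cols), dropped)


@dataclass
class HaplotypeSet:
    """Distinct sequences with their member samples; exact identity defines a haplotype.

    Ambiguity codes and gaps are ordinary characters here: ``ACGT`` and ``ACGN``
    are two haplotypes.  Haplotypes are ordered by descending count, then first
    occurrence, and named H1, H2, ...
    """

    sequences: list[str]
    membership: list[list[str]]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [f"H{i + 1}" for i in range(len(self.sequences))]

    @property
    def counts(self) -> list[int]:
        return [len(m) for m in self.membership]

    @property
    def n_samples(self) -> int:
        return sum(self.counts)

    def sequence_of(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    def members_of(self, name: str) -> list[str]:
        return self.membership[self.names.index(name)]


def collapse_haplotypes(aln: Alignment, ids: list[str] | None = None) -> HaplotypeSet:
    """Group samples sharing byte-identical aligned sequences."""
    if ids is None:
        ids = list(aln.sample_ids)
    if not ids:
        raise AlignmentError("collapse_haplotypes: empty id set")
    sub = aln.subset(ids)
    seen: OrderedDict[str, list[str]] = OrderedDict()
    for sid, row in zip(sub.sample_ids, sub.rows):
        seen.setdefault(row, []).append(sid)
    ordered = sorted(seen.items(), key=lambda kv: (-len(kv[1]), ids.index(kv[1][0])))
    return HaplotypeSet([s for s, _ in ordered], [m for _, m in ordered])


def consensus_sequence(aln: Alignment, ids: list[str] | None = None, plurality: float = 0.5) -> str:
    """Per-column plurality consensus with IUPAC fallback.

    The most frequent unambiguous base wins a column if it is a unique maximum
    with frequency >= ``plurality`` among non-gap unambiguous calls; otherwise
    the minimal IUPAC code covering all bases at >= 25% frequency is emitted
    (ties at the plurality threshold therefore fall through to the IUPAC code).
    All-gap columns yield '-'; columns with only ambiguous calls yield 'N'.
    """
    if ids is None:
        ids = list(aln.sample_ids)
    if not ids:
        raise AlignmentError("consensus_sequence: empty id set")
    sub = aln.subset(ids)
    out = []
    for j in range(sub.L):
        col = [row[j] for row in sub.rows]
        nongap = [c for c in col if c != "-"]
        if not nongap:
            out.append("-")
            continue
        plain = [c for c in nongap if c in UNAMBIGUOUS]
        if not plain:
            out.append("N")
            continue
        tally = Counter(plain)
        total = len(plain)
        best_count = max(tally.values())
        winners = [b for b, c in tally.items() if c == best_count]
        if len(winners) == 1 and best_count / total >= plurality:
            out.append(winners[0])
        else:
            covered = frozenset(b for b, c in tally.items() if c / total >= 0.25)
            if not covered:
                covered = frozenset(winners)
            out.append(BASES_TO_IUPAC[covered])
    return "".join(out)


# --- diagnostic-site classification -----------------------------------------

FIXED_DIFFERENCE = "fixed_difference"
AUTAPOMORPHY = "autapomorphy"
SHARED_ANCESTRAL = "shared_ancestral"
VARIABLE_UNINFORMATIVE = "variable_uninformative"


def detect_diagnostic_sites(aln: Alignment, table: SampleTable) -> pd.DataFrame:
    """Classify every variable alignment column against the group labels.

    Classes (mutually exclusive, in priority order):

    - ``fixed_difference``: every target carries one state s and no nontarget
      carries s;
    - ``autapomorphy``: a minority state carried only by samples sharing one
      identical full-length sequence (so duplicated rows do not erase it);
      the owning sample is the first carrier;
    - ``shared_ancestral``: all targets share a state equal to the outgroup
      state while some nontarget differs;
    - ``variable_uninformative``: any other variable column.

    Columns where any compared sample carries a gap or ambiguity code are
    flagged ``low_confidence`` (degraded museum material produces them) but are
    still classified from their unambiguous calls.
    """
    table.validate_against(aln)
    groups = {s: table.group_of(s) for s in aln.sample_ids}
    present = set(groups.values())
    if len(present) < 2:
        raise MetadataError("detect_diagnostic_sites needs at least two groups")
    rows_out = []
    for j in range(aln.L):
        col = {s: aln.row(s)[j] for s in aln.sample_ids}
        plain = {s: c for s, c in col.items() if c in UNAMBIGUOUS}
        low_conf = len(plain) < len(col)
        states = set(plain.values())
        if len(states) <= 1:
            continue  # invariant (among unambiguous calls): not reported
        tgt = {c for s, c in plain.items() if groups[s] == "target"}
        non = {c for s, c in plain.items() if groups[s] == "nontarget"}
        out = {c for s, c in plain.items() if groups[s] == "outgroup"}
        classification = VARIABLE_UNINFORMATIVE
        owner = ""
        if len(tgt) == 1 and tgt and non and not (tgt & non):
            classification = FIXED_DIFFERENCE
        else:
            state_counts = Counter(plain.values())
            minority = [c for c, k in state_counts.items() if k < len(plain) / 2]
            for state in sorted(minority):
                carriers = [s for s, c in plain.items() if c == state]
                carrier_seqs = {aln.row(s) for s in carriers}
                if len(carrier_seqs) == 1:
                    classification = AUTAPOMORPHY
                    owner = carriers[0]
                    break
            if classification == VARIABLE_UNINFORMATIVE and len(tgt) == 1 and len(out) == 1 and tgt == out and non - tgt:
                classification = SHARED_ANCESTRAL
        rows_out.append(
            {
                "position": j + 1,
                "target_states": "".join(sorted(tgt)),
                "nontarget_states": "".join(sorted(non)),
                "outgroup_states": "".join(sorted(out)),
                "classification": classification,
                "owner": owner,
                "low_confidence": low_conf,
            }
        )
    return pd.DataFrame(
        rows_out,
        columns=[
            "position", "target_states", "nontarget_states", "outgroup_states",
            "classification", "owner", "low_confidence",
        ],
    )
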