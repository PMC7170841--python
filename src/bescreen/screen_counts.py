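"""From sequencing reads (or ready-made tables) to filtered guide counts.

Reads trimmed to the 20-nt variable region are matched exactly against the
library; a read one mismatch away from exactly one guide is recorded as a
mismatch variant of that guide.  Variants claiming more than 7.5% of a
guide's perfectly-aligned reads are too abundant to be sequencing noise and
are re-labelled synthesis-error (SE) guides: oligo-synthesis by-products
that carry no editing activity and therefore double as negative controls
for the fitness statistics (when sufficiently abundant, > 1000 reads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

SE_RATIO_THRESHOLD = 0.075
ABUNDANT_SE_READS = 1000


class CountError(ValueError):
    pass


@dataclass
class CountTable:
    """Integer guide × sample read counts with sample metadata.

    ``samples`` is indexed by sample name with columns ``timepoint``
    (``T0_mutagenesis`` / ``T_end``) and ``replicate`` (``A`` / ``B``).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise CountError("count columns and sample metadata disagree")
        if (self.counts.to_numpy() < 0).any():
            raise CountError("negative counts")
        self.counts = self.counts.astype(int)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample_names(self, timepoint: str) -> list[str]:
        return list(self.samples.index[self.samples["timepoint"] == timepoint])

    def replicates(self) -> list[str]:
        return sorted(self.samples["replicate"].unique())


def make_sample_frame(sample_names: Iterable[str]) -> pd.DataFrame:
    """Parse names like 'T0_mutagenesis:A' into a sample-metadata frame."""
    rows = []
    for name in sample_names:
        timepoint, _, replicate = name.rpartition(":")
        if not timepoint:
            raise CountError(f"sample name {name!r} is not 'timepoint:replicate'")
        rows.append({"sample": name, "timepoint": timepoint, "replicate": replicate})
    return pd.DataFrame(rows).set_index("sample")


@dataclass(frozen=True)
class MismatchRecord:
    parent_guide_id: str
    variant_sequence: str
    position: int            # 0-based index within the 20-mer
    observed_base: str


@dataclass
class SEGuideSet:
    """Mismatch variants promoted to synthesis-error guides."""

    records: list[MismatchRecord] = field(default_factory=list)
    total_reads: dict[str, int] = field(default_factory=dict)  # variant seq → reads
    abundant: set[str] = field(default_factory=set)            # variant seqs

    def variant_ids(self) -> dict[str, str]:
        return {
            r.variant_sequence:
                f"{r.parent_guide_id}_SE_{r.position}{r.observed_base}"
            for r in self.records
        }


def _mask_index(library: Mapping[str, str]) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for gid, seq in library.items():
        for i in range(len(seq)):
            index.setdefault(seq[:i] + "*" + seq[i + 1 :], []).append(gid)
    return index


def match_reads(
    reads: Iterable[str], library: Mapping[str, str]
) -> tuple[Counter, Counter, int]:
    """Assign reads to guides exactly or at Hamming distance 1.

    Returns (perfect counts by guide_id, mismatch counts by
    (parent_guide_id, position, base), unassigned count).  Reads matching
    more than one guide at distance 1, of the wrong length, or with no
    match are unassigned.  Conservation: perfect + mismatch + unassigned
    equals the number of input reads.
    """
    exact = {seq: gid for gid, seq in library.items()}
    if len(exact) != len(library):
        raise CountError("duplicate protospacer sequences in the library")
    read_len = len(next(iter(exact))) if exact else 20
    masks = _mask_index(library)
    perfect: Counter = Counter()
    mismatches: Counter = Counter()
    unassigned = 0
    for read in reads:
        read = read.upper()
        if len(read) != read_len:
            unassigned += 1
            continue
        gid = exact.get(read)
        if gid is not None:
            perfect[gid] += 1
            continue
        hits: set[str] = set()
        hit_pos = -1
        for i in range(read_len):
            for cand in masks.get(read[:i] + "*" + read[i + 1 :], ()):
                hits.add(cand)
                hit_pos = i
        if len(hits) == 1:
            parent = hits.pop()
            mismatches[(parent, hit_pos, read[hit_pos])] += 1
        else:
            unassigned += 1
    return perfect, mismatches, unassigned


def count_samples(
    reads_by_sample: Mapping[str, Iterable[str]],
    library: Mapping[str, str],
) -> tuple[CountTable, pd.DataFrame, dict[str, int]]:
    """Run match_reads per sample and assemble tables.

    Returns (perfect CountTable, mismatch table indexed by
    (parent, position, base) with one column per sample, unassigned per
    sample).
    """
    sample_names = list(reads_by_sample)
    perfect_cols, mm_cols, unassigned = {}, {}, {}
    for name in sample_names:
        p, m, u = match_reads(reads_by_sample[name], library)
        perfect_cols[name] = p
        mm_cols[name] = m
        unassigned[name] = u
    counts = pd.DataFrame(perfect_cols).reindex(sorted(library)).fillna(0).astype(int)
    counts.index.name = "guide_id"
    all_mm = sorted(set().union(*[m.keys() for m in mm_cols.values()]) or set())
    mm = pd.DataFrame(
        {name: [mm_cols[name].get(k, 0) for k in all_mm] for name in sample_names},
        index=pd.MultiIndex.from_tuples(
            all_mm, names=["parent_guide_id", "position", "base"]
        ) if all_mm else pd.MultiIndex.from_arrays(
            [[], [], []], names=["parent_guide_id", "position", "base"]
        ),
    ).astype(int)
    table = CountTable(counts=counts, samples=make_sample_frame(sample_names))
    return table, mm, unassigned


def detect_synthesis_errors(
    mismatch_table: pd.DataFrame,
    table: CountTable,
    library: Mapping[str, str],
    ratio_threshold: float = SE_RATIO_THRESHOLD,
    abundant_reads: int = ABUNDANT_SE_READS,
) -> tuple[SEGuideSet, CountTable, pd.Series]:
    """Split mismatch variants into synthesis errors vs sequencing errors.

    Ratios use totals aggregated over all samples.  SE variants keep their
    reads as separate guide rows (id ``<parent>_SE_<pos><base>``); non-SE
    mismatch reads are credited back to the parent guide.  Returns the SE
    set, the corrected CountTable, and a boolean is_se flag per output row.
    """
    perfect_totals = table.counts.sum(axis=1)
    se = SEGuideSet()
    corrected = table.counts.copy()
    se_rows: dict[str, pd.Series] = {}
    for key, row in mismatch_table.iterrows():
        parent, pos, base = key
        variant_total = int(row.sum())
        parent_total = int(perfect_totals.get(parent, 0))
        is_se = (
            parent_total == 0 or variant_total / parent_total > ratio_threshold
        )
        seq = library[parent]
        variant_seq = seq[:pos] + base + seq[pos + 1 :]
        if is_se:
            rec = MismatchRecord(parent, variant_seq, int(pos), str(base))
            se.records.append(rec)
            se.total_reads[variant_seq] = variant_total
            if variant_total > abundant_reads:
                se.abundant.add(variant_seq)
            vid = f"{parent}_SE_{pos}{base}"
            se_rows[vid] = row
        else:
            corrected.loc[parent] = corrected.loc[parent] + row
    if se_rows:
        corrected = pd.concat(
            [corrected, pd.DataFrame(se_rows).T.astype(int)]
        )
        corrected.index.name = table.counts.index.name
    abundant_ids = {
        f"{r.parent_guide_id}_SE_{r.position}{r.observed_base}"
        for r in se.records if r.variant_sequence in se.abundant
    }
    is_se_flag = pd.Series(
        [gid in set(se_rows) for gid in corrected.index], index=corrected.index,
        name="is_se",
    )
    # only abundant SE rows are retained as controls; rare SE reads are dropped
    keep = [
        gid for gid in corrected.index
        if gid not in set(se_rows) or gid in abundant_ids
    ]
    corrected = corrected.loc[keep]
    is_se_flag = is_se_flag.loc[keep]
    out = CountTable(counts=corrected, samples=table.samples.copy())
    return se, out, is_se_flag


def filter_presence(table: CountTable) -> CountTable:
    """Drop guides absent (zero) from strictly more than half of the samples."""
    n = table.counts.shape[1]
    if n < 2:
        raise CountError("presence filter needs >= 2 samples")
    zeros = (table.counts == 0).sum(axis=1)
    keep = zeros <= n / 2
    return CountTable(counts=table.counts.loc[keep].copy(),
                      samples=table.samples.copy())


def filter_min_reads(
    table: CountTable,
    timepoint: str = "T0_mutagenesis",
    threshold: int = 54,
) -> pd.Index:
    """Guides with >= ``threshold`` reads in *every* replicate at ``timepoint``."""
    cols = table.sample_names(timepoint)
    if not cols:
        raise CountError(f"no samples at timepoint {timepoint!r}")
    reps = set(table.samples.loc[cols, "replicate"])
    if reps != set(table.replicates()):
        raise CountError(f"timepoint {timepoint!r} missing a replicate")
    ok = (table.counts[cols] >= threshold).all(axis=1)
    return table.counts.index[ok]


def read_count_table(path) -> CountTable:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(counts=counts, samples=make_sample_frame(counts.columns))


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t")
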