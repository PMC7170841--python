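"""Target-AID protospacer enumeration and library-design filters.

PAM-relative convention: position ``-k`` is the base k positions 5' of the
first PAM base, so ``-1`` abuts the PAM and ``-20`` is the protospacer 5'
end.  String index ``i`` of the 20-nt protospacer therefore corresponds to
position ``-(20 - i)``.

The deaminase acts in an extended window spanning positions -20..-14, with
the bulk of its activity at -19..-17 (the "high-activity" window).  Library
design requires at least one editable cytosine in the high window and
rejects sites where co-editing would scramble the genotype-to-guide link:
all three of {-19,-18,-17} C, or the -18/-17 pair both C.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .sequence_io import CDS_CLASSES, GeneModel, ReferenceSet, revcomp

EXTENDED_WINDOW = tuple(range(-20, -13))   # -20 .. -14
HIGH_WINDOW = (-19, -18, -17)

#: Relative editing-activity weights per PAM-relative position.  Only the
#: ordering is contractual (it reproduces the known activity ranking of the
#: editor); the numeric values are an editable parameterisation.
DEFAULT_ACTIVITY_WEIGHTS: dict[int, float] = {
    -18: 1.0, -17: 0.9, -19: 0.8, -16: 0.3, -15: 0.1, -20: 0.1, -14: 0.05,
}

RISK_CATEGORIES = ("very_low", "low", "moderate", "high")

#: Seeded pattern table: 7-mer over positions -20..-14, alphabet
#: {N: any, D: not-C, C}.  Only the unambiguous anchor is shipped; the
#: algorithmic fallback below handles everything else.
DEFAULT_RISK_PATTERNS: dict[str, str] = {"NCDDDNN": "very_low"}

BSAI_SITE = "GGTCTC"


class DesignError(ValueError):
    pass


def pos_to_index(pos: int) -> int:
    """PAM-relative position (-20..-1) → protospacer string index (0..19)."""
    if not -20 <= pos <= -1:
        raise DesignError(f"PAM-relative position {pos} outside -20..-1")
    return 20 + pos


def index_to_pos(i: int) -> int:
    return i - 20


@dataclass
class DesignConfig:
    extended_window: tuple[int, ...] = EXTENDED_WINDOW
    high_window: tuple[int, ...] = HIGH_WINDOW
    cds_fraction_bounds: tuple[float, float] = (0.005, 0.75)
    forbidden_sites: tuple[str, ...] = (BSAI_SITE, revcomp(BSAI_SITE))
    nag_excluded: bool = True
    risk_patterns: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RISK_PATTERNS)
    )
    activity_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_WEIGHTS)
    )

    def validate(self) -> None:
        lo, hi = self.cds_fraction_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise DesignError(
                f"cds_fraction_bounds {self.cds_fraction_bounds} must be "
                "an increasing pair within [0, 1]"
            )
        if not set(self.high_window) <= set(self.extended_window):
            raise DesignError("high window must lie inside the extended window")
        for cat in self.risk_patterns.values():
            if cat not in RISK_CATEGORIES:
                raise DesignError(f"unknown risk category {cat!r}")


@dataclass
class GuideRecord:
    guide_id: str
    protospacer: str
    pam: str
    chrom: str
    protospacer_strand: str
    strand_class: str                     # coding / noncoding vs target gene
    pam_genomic_start: int                # genomic coord of first PAM base (+ strand layout)
    pam_relative_c_positions: tuple[int, ...]
    high_window_c: tuple[int, ...]
    gene_id: str
    target_class: str
    risk_category: Optional[str] = None
    cds_fraction: Optional[float] = None

    def genomic_position(self, pos: int) -> int:
        """Genomic (+ strand) coordinate of PAM-relative position ``pos``."""
        if self.protospacer_strand == "+":
            return self.pam_genomic_start + pos      # pos is negative
        return self.pam_genomic_start - pos          # mirrored on the minus strand


def editable_cytosines(
    protospacer: str, config: DesignConfig | None = None
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """PAM-relative positions of Cs in the extended and high windows."""
    config = config or DesignConfig()
    if len(protospacer) != 20:
        raise DesignError(f"protospacer length {len(protospacer)} != 20")
    ext = tuple(
        p for p in sorted(config.extended_window)
        if protospacer[pos_to_index(p)] == "C"
    )
    high = tuple(p for p in ext if p in config.high_window)
    return ext, high


def enumerate_candidates(
    reference: ReferenceSet, config: DesignConfig | None = None
) -> list[GuideRecord]:
    """Emit every NGG-adjacent 20-mer whose protospacer overlaps a gene.

    Unfiltered: records carry window annotations but no risk category or
    pass/fail status yet.  A protospacer is attributed to a gene when any
    of its extended-window positions falls inside the gene's intervals.
    """
    config = config or DesignConfig()
    config.validate()
    out: list[GuideRecord] = []
    for gene in reference.genes:
        chrom_seq = reference.sequences[gene.chrom]
        lo, hi = gene.span
        # scan a margin wide enough for any protospacer touching the gene
        scan_lo, scan_hi = max(0, lo - 26), min(len(chrom_seq), hi + 26)
        for strand in "+-":
            for pam_start, proto in _scan_strand(chrom_seq, scan_lo, scan_hi, strand):
                ext, high = editable_cytosines(proto, config)
                rec = GuideRecord(
                    guide_id="",
                    protospacer=proto,
                    pam=_pam_seq(chrom_seq, pam_start, strand),
                    chrom=gene.chrom,
                    protospacer_strand=strand,
                    strand_class="coding" if strand == gene.strand else "noncoding",
                    pam_genomic_start=pam_start,
                    pam_relative_c_positions=ext,
                    high_window_c=high,
                    gene_id=gene.gene_id,
                    target_class=gene.target_class,
                )
                if any(gene.contains(rec.genomic_position(p))
                       for p in sorted(config.extended_window)):
                    out.append(rec)
    for i, rec in enumerate(out):
        rec.guide_id = f"g{i:05d}"
    return out


def _scan_strand(chrom_seq: str, lo: int, hi: int, strand: str):
    """Yield (pam_genomic_start, protospacer) for NGG PAMs on one strand.

    ``pam_genomic_start`` is the + strand coordinate of the first PAM base
    as seen 5'→3' on the protospacer strand.
    """
    if strand == "+":
        for m in re.finditer(r"(?=[ACGT]GG)", chrom_seq[lo:hi]):
            p = lo + m.start()
            if p >= 20:
                yield p, chrom_seq[p - 20 : p]
    else:
        for m in re.finditer(r"(?=CC[ACGT])", chrom_seq[lo:hi]):
            p = lo + m.start()          # + strand CCN start; PAM base N at p+2 on -
            if p + 23 <= len(chrom_seq):
                yield p + 2, revcomp(chrom_seq[p + 3 : p + 23])


def _pam_seq(chrom_seq: str, pam_start: int, strand: str) -> str:
    if strand == "+":
        return chrom_seq[pam_start : pam_start + 3]
    return revcomp(chrom_seq[pam_start - 2 : pam_start + 1])


def count_genome_matches(
    reference: ReferenceSet, protospacer: str, pam_pattern: str = "GG"
) -> int:
    """Exact occurrences of protospacer followed by N+``pam_pattern``, both strands."""
    total = 0
    targets = [protospacer + "[ACGT]" + pam_pattern]
    targets.append(
        revcomp(protospacer + "N" + pam_pattern).replace("N", "[ACGT]")
    )
    for seq in reference.sequences.values():
        for pat in targets:
            total += len(re.findall(f"(?={pat})", seq))
    return total


def count_nag_matches(reference: ReferenceSet, protospacer: str) -> int:
    return count_genome_matches(reference, protospacer, pam_pattern="AG")


def rank_target_cs(high_window_c: Iterable[int], config: DesignConfig) -> list[int]:
    """High-window Cs ordered by activity weight, ties toward the PAM."""
    return sorted(high_window_c, key=lambda p: (-config.activity_weights[p], -p))


def cds_position_fraction(
    candidate: GuideRecord, gene: GeneModel, config: DesignConfig | None = None
) -> float:
    """(1-based CDS coordinate of the top-ranked target C) / CDS length."""
    config = config or DesignConfig()
    if not candidate.high_window_c:
        raise DesignError(f"{candidate.guide_id}: no high-window C")
    top = rank_target_cs(candidate.high_window_c, config)[0]
    cds_idx = gene.genomic_to_cds(candidate.genomic_position(top))
    if cds_idx is None:
        raise DesignError(
            f"{candidate.guide_id}: target C not inside the CDS of {gene.gene_id}"
        )
    return (cds_idx + 1) / gene.cds_length


def apply_design_filters(
    candidate: GuideRecord,
    reference: ReferenceSet,
    config: DesignConfig | None = None,
) -> tuple[bool, list[str]]:
    """Evaluate every library-design rule; reasons list each failed rule."""
    config = config or DesignConfig()
    reasons: list[str] = []
    high = set(candidate.high_window_c)
    if not high:
        reasons.append("no_high_window_c")
    if {-19, -18, -17} <= high:
        reasons.append("all_three_high")
    if {-18, -17} <= high:
        reasons.append("pair_18_17")
    if len(high) >= 3:
        # redundant with all_three_high for a 3-position window; kept as its
        # own rule so a reconfigured window stays covered
        if "all_three_high" not in reasons:
            reasons.append("three_in_high_window")
    for motif in config.forbidden_sites:
        if motif in candidate.protospacer:
            reasons.append("bsai")
            break
    n_matches = count_genome_matches(reference, candidate.protospacer)
    if n_matches != 1:
        reasons.append("not_unique")
    if config.nag_excluded and count_nag_matches(reference, candidate.protospacer) > 0:
        reasons.append("nag_site")
    if candidate.target_class in CDS_CLASSES and high:
        gene = reference.gene(candidate.gene_id)
        try:
            frac = cds_position_fraction(candidate, gene, config)
        except DesignError:
            reasons.append("edit_outside_cds")
        else:
            candidate.cds_fraction = frac
            lo, hi_b = config.cds_fraction_bounds
            if not (lo <= frac <= hi_b):
                reasons.append("cds_fraction")
    return (not reasons, reasons)


def _matches_pattern(window7: str, pattern: str) -> bool:
    for base, sym in zip(window7, pattern):
        if sym == "N":
            continue
        if sym == "C" and base != "C":
            return False
        if sym == "D" and base == "C":
            return False
    return True


def assign_risk_category(
    window7: str, config: DesignConfig | None = None
) -> str:
    """Co-editing risk from the 7-nt window over positions -20..-14.

    First consult the configured pattern table; otherwise fall back to an
    activity-weight rule: the primary (highest-weight) C is the intended
    edit, and the category grows with the number and weight of secondary
    Cs that could be co-edited.
    """
    config = config or DesignConfig()
    if len(window7) != 7:
        raise DesignError(f"risk window length {len(window7)} != 7")
    for pattern, category in config.risk_patterns.items():
        if _matches_pattern(window7, pattern):
            return category
    window_positions = sorted(config.extended_window)  # -20..-14 ↔ index 0..6
    cs = [window_positions[i] for i, b in enumerate(window7) if b == "C"]
    if not cs:
        raise DesignError("no C in risk window; guide should not be in the library")
    weights = config.activity_weights
    primary = max(cs, key=lambda p: (weights[p], p))
    secondary = [p for p in cs if p != primary]
    if not secondary:
        return "very_low"
    if any(p in config.high_window for p in secondary):
        return "high"
    if any(abs(a - b) == 1 for a in cs for b in cs if a != b):
        return "high"  # CC dinucleotide invites processive co-editing
    if any(weights[p] > 0.1 for p in secondary):
        return "moderate"
    return "low"


def build_library(
    reference: ReferenceSet, config: DesignConfig | None = None
) -> tuple[list[GuideRecord], pd.DataFrame]:
    """Run enumeration + filters + risk assignment; return (library, report).

    The report tallies candidates per target class, risk category, rejection
    reason and editable-C count.  Output order is deterministic.
    """
    config = config or DesignConfig()
    config.validate()
    candidates = enumerate_candidates(reference, config)
    kept: list[GuideRecord] = []
    tallies: dict[str, int] = {"candidates": len(candidates)}
    for cand in candidates:
        ok, reasons = apply_design_filters(cand, reference, config)
        if not ok:
            for r in reasons:
                tallies[f"rejected_{r}"] = tallies.get(f"rejected_{r}", 0) + 1
            continue
        window7 = "".join(
            cand.protospacer[pos_to_index(p)] for p in sorted(config.extended_window)
        )
        cand.risk_category = assign_risk_category(window7, config)
        kept.append(cand)
    kept.sort(key=lambda g: (g.chrom, g.pam_genomic_start, g.protospacer_strand,
                             g.gene_id))
    for i, g in enumerate(kept):
        g.guide_id = f"guide{i:05d}"
    tallies["library_size"] = len(kept)
    for g in kept:
        for key in (f"class_{g.target_class}", f"risk_{g.risk_category}",
                    f"c_count_{len(g.pam_relative_c_positions)}"):
            tallies[key] = tallies.get(key, 0) + 1
    report = pd.DataFrame(
        sorted(tallies.items()), columns=["metric", "count"]
    )
    return kept, report


LIBRARY_COLUMNS = [
    "guide_id", "protospacer", "pam", "chrom", "protospacer_strand",
    "strand_class", "pam_genomic_start", "pam_relative_c_positions",
    "high_window_c", "risk_category", "gene_id", "cds_fraction",
    "target_class",
]


def library_to_frame(guides: list[GuideRecord]) -> pd.DataFrame:
    rows = []
    for g in guides:
        rows.append({
            "guide_id": g.guide_id,
            "protospacer": g.protospacer,
            "pam": g.pam,
            "chrom": g.chrom,
            "protospacer_strand": g.protospacer_strand,
            "strand_class": g.strand_class,
            "pam_genomic_start": g.pam_genomic_start,
            "pam_relative_c_positions": ",".join(map(str, g.pam_relative_c_positions)),
            "high_window_c": ",".join(map(str, g.high_window_c)),
            "risk_category": g.risk_category,
            "gene_id": g.gene_id,
            "cds_fraction": g.cds_fraction,
            "target_class": g.target_class,
        })
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library(guides: list[GuideRecord], path) -> None:
    library_to_frame(guides).to_csv(path, sep="\t", index=False)
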