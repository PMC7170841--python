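"""Per-guide mutational outcome prediction and guide physical features.

The outcome model is deliberately parsimonious: the deaminase mostly
produces single-nucleotide C→G or C→T changes (C→A is negligible), and when
several window cytosines are editable the per-position editing frequency
follows the editor's known activity ranking.  The "model set" for a guide
is therefore the C→G and C→T genotypes at the top-ranked editable C, plus
the same pair at the second-ranked C when one exists — at most four
genotypes per guide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .guide_design import DEFAULT_ACTIVITY_WEIGHTS, GuideRecord

from .sequence_io import GeneModel, ReferenceSet, revcomp, translate_cds

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class OutcomeError(ValueError):
    pass


@dataclass
class ActivityProfile:
    """Relative editing-activity weight per PAM-relative window position."""

    weight: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weight.values()):
            raise OutcomeError("activity weights must be non-negative")
        high = [self.weight.get(p, 0.0) for p in (-19, -18, -17)]
        rest = [w for p, w in self.weight.items() if p not in (-19, -18, -17)]
        if rest and min(high) <= max(rest):
            raise OutcomeError("high-window weights must exceed all others")


def rank_positions(
    c_positions: Iterable[int], profile: ActivityProfile | None = None
) -> list[int]:
    """Order editable-C positions by descending activity, ties toward the PAM."""
    profile = profile or ActivityProfile()
    return sorted(c_positions, key=lambda p: (-profile.weight.get(p, 0.0), -p))


@dataclass
class EditGenotype:
    """A set of base changes on the protospacer strand plus its consequence."""

    edits: tuple[tuple[int, str, str], ...]   # (pam-relative pos, ref C, alt)
    coding_changes: tuple[tuple[int, str, str], ...] = ()  # (CDS pos, ref, alt)
    aa_changes: tuple[tuple[int, str, str], ...] = ()      # (1-based residue, ref, alt)
    consequence: Optional[str] = None
    target_residue: Optional[tuple[int, str]] = None       # (1-based index, ref AA)

    def __post_init__(self) -> None:
        for _, ref, alt in self.edits:
            if ref != "C":
                raise OutcomeError("edited reference base must be C on the "
                                   "protospacer strand")
            if alt not in "GTA":
                raise OutcomeError(f"alt base {alt!r} not one of G/T/A")

    @property
    def key(self) -> str:
        """Canonical label, e.g. '-18C>G' or '-18C>G;-16C>T'."""
        return ";".join(f"{p}C>{alt}" for p, _, alt in sorted(self.edits))


def genotype_key(edits: Sequence[tuple[int, str]]) -> str:
    """Canonical label from (position, alt) pairs."""
    return ";".join(f"{p}C>{alt}" for p, alt in sorted(edits))


def _apply_edits_to_cds(
    guide: GuideRecord,
    gene: GeneModel,
    reference: ReferenceSet,
    edits: Sequence[tuple[int, str, str]],
) -> tuple[tuple, tuple, str, Optional[tuple[int, str]]]:
    """Map protospacer-strand edits to CDS changes and classify them."""
    if gene.target_class == "intron":
        return (), (), "intron", None
    chrom_seq = reference.sequences[guide.chrom]
    cds = gene.cds_sequence(chrom_seq)
    protein = translate_cds(cds)
    mutated = list(cds)
    coding_changes = []
    for pos, _ref, alt in edits:
        gpos = guide.genomic_position(pos)
        cds_idx = gene.genomic_to_cds(gpos)
        if cds_idx is None:
            raise OutcomeError(
                f"{guide.guide_id}: edit at {guide.chrom}:{gpos} outside the "
                f"CDS of {gene.gene_id}"
            )
        # protospacer strand agrees with the coding strand iff strand_class
        # is coding; otherwise the change appears complemented on the mRNA
        if guide.strand_class == "coding":
            ref_c, alt_c = "C", alt
        else:
            ref_c, alt_c = "G", _COMP[alt]
        if cds[cds_idx] != ref_c:
            raise OutcomeError(
                f"{guide.guide_id}: reference mismatch at CDS {cds_idx} "
                f"({cds[cds_idx]} != {ref_c})"
            )
        mutated[cds_idx] = alt_c
        coding_changes.append((cds_idx, ref_c, alt_c))
    new_protein = translate_cds("".join(mutated))
    aa_changes = tuple(
        (i + 1, a, b) for i, (a, b) in enumerate(zip(protein, new_protein)) if a != b
    )
    if any(b == "*" for _, _, b in aa_changes):
        consequence = "nonsense"
    elif len(aa_changes) >= 2:
        consequence = "multi"
    elif len(aa_changes) == 1:
        consequence = "missense"
    else:
        consequence = "silent"
    res_idx = coding_changes[0][0] // 3
    target_residue = (res_idx + 1, protein[res_idx])
    return tuple(coding_changes), aa_changes, consequence, target_residue


def annotate_consequence(
    genotype: EditGenotype,
    guide: GuideRecord,
    gene: GeneModel,
    reference: ReferenceSet,
) -> EditGenotype:
    coding, aa, consequence, residue = _apply_edits_to_cds(
        guide, gene, reference, genotype.edits
    )
    genotype.coding_changes = coding
    genotype.aa_changes = aa
    genotype.consequence = consequence
    genotype.target_residue = residue
    return genotype


def predict_outcomes(
    guide: GuideRecord,
    gene: GeneModel,
    reference: ReferenceSet,
    profile: ActivityProfile | None = None,
) -> list[EditGenotype]:
    """The ranked model set: C→G/C→T at the top one or two editable Cs."""
    profile = profile or ActivityProfile()
    if not guide.high_window_c:
        raise OutcomeError(f"{guide.guide_id}: no high-window C")
    ranked = rank_positions(guide.pam_relative_c_positions, profile)
    out = []
    for pos in ranked[:2]:
        for alt in ("G", "T"):
            g = EditGenotype(edits=((pos, "C", alt),))
            annotate_consequence(g, guide, gene, reference)
            out.append(g)
    return out


@dataclass
class SggClass:
    """A stop-codon-generating guide's target codon and route to the stop."""

    codon: str               # on the coding strand
    stop_via: str            # 'C>G' or 'C>T' (protospacer-strand edit)
    rank: int                # 1 = stop arises at the top-ranked position
    strand_note: Optional[str] = None


def classify_sgg(
    guide: GuideRecord,
    gene: GeneModel,
    reference: ReferenceSet,
    profile: ActivityProfile | None = None,
) -> Optional[SggClass]:
    """Return the stop-generating classification, or None for non-SGGs."""
    outcomes = predict_outcomes(guide, gene, reference, profile)
    ranked_pos = []
    for g in outcomes:
        p = g.edits[0][0]
        if p not in ranked_pos:
            ranked_pos.append(p)
    for g in outcomes:
        if g.consequence != "nonsense":
            continue
        pos, _, alt = g.edits[0]
        cds = gene.cds_sequence(reference.sequences[guide.chrom])
        stop_res = next(i for i, _, b in g.aa_changes if b == "*")
        codon = cds[(stop_res - 1) * 3 : stop_res * 3]
        note = None
        if guide.strand_class == "noncoding":
            note = f"targeted on the non-coding strand as {revcomp(codon)}"
        return SggClass(
            codon=codon,
            stop_via=f"C>{alt}",
            rank=ranked_pos.index(pos) + 1,
            strand_note=note,
        )
    return None


def guide_features(
    guide: GuideRecord | str,
    nn_table: Optional[Mapping] = None,
    Na: float = 50.0,
    dnac1: float = 25.0,
    dnac2: float = 25.0,
) -> dict[str, float]:
    """RNA:DNA duplex melting temperature and base-composition features.

    Tm comes from a nearest-neighbor computation with the published RNA/DNA
    hybrid parameter set (Sugimoto et al.); the table is swappable.
    """
    proto = guide.protospacer if isinstance(guide, GuideRecord) else guide
    bad = set(proto) - set("ACGT")
    if bad:
        raise OutcomeError(f"non-ACGT base(s) in protospacer: {sorted(bad)}")
    table = nn_table if nn_table is not None else _mt.R_DNA_NN1
    tm = _mt.Tm_NN(proto, nn_table=table, Na=Na, dnac1=dnac1, dnac2=dnac2)
    n = len(proto)
    return {
        "duplex_tm": float(tm),
        "gc_fraction": (proto.count("G") + proto.count("C")) / n,
        "c_fraction": proto.count("C") / n,
        "g_fraction": proto.count("G") / n,
    }


def model_coverage(
    observed: Mapping[str, float], model_set: Iterable[str]
) -> float:
    """Fraction of edited reads explained by the model-set genotypes."""
    total = float(sum(observed.values()))
    if total <= 0:
        raise OutcomeError("model coverage undefined: zero edited reads")
    model = set(model_set)
    return sum(v for k, v in observed.items() if k in model) / total


def single_edit_universe(
    c_positions: Iterable[int], alts: str = "GTA"
) -> list[str]:
    """All single-edit genotype keys over the window Cs (C→G/T/A)."""
    return [genotype_key([(p, a)]) for p in sorted(c_positions) for a in alts]


def random_combination_percentile(
    observed: Mapping[str, float],
    c_positions: Iterable[int],
    k: int,
    q: float = 99.0,
    n_samples: int = 10000,
    seed: int = 0,
    exhaustive_cap: int = 50000,
) -> float:
    """Coverage of the q-th percentile k-subset of single-edit genotypes.

    Enumerate all C(n, k) subsets of the single-edit genotype universe when
    feasible, otherwise draw ``n_samples`` random subsets; return the q-th
    percentile of their coverages.  This is the yardstick a guide's model
    set must beat to count as predictive.
    """
    universe = single_edit_universe(c_positions)
    n = len(universe)
    if k > n:
        raise OutcomeError(f"k={k} exceeds the {n}-genotype universe")
    total = float(sum(observed.values()))
    if total <= 0:
        raise OutcomeError("percentile undefined: zero edited reads")
    from math import comb

    coverages: list[float] = []
    if comb(n, k) <= exhaustive_cap:
        for subset in itertools.combinations(universe, k):
            coverages.append(
                sum(observed.get(g, 0.0) for g in subset) / total
            )
    else:
        rng = np.random.default_rng(seed)
        idx = np.arange(n)
        for _ in range(n_samples):
            pick = rng.choice(idx, size=k, replace=False)
            coverages.append(
                sum(observed.get(universe[i], 0.0) for i in pick) / total
            )
    return float(np.percentile(coverages, q))


def rank_agreement_test(
    predicted_ranks: Sequence[Sequence[int]],
    observed_ranks: Sequence[Sequence[int]],
    n_perm: int = 100000,
    seed: int = 0,
) -> tuple[int, float]:
    """Permutation test of predicted-vs-observed editing ranks.

    The statistic is the number of sites whose predicted rank equals the
    observed rank.  Observed ranks are permuted within each guide;
    p = (1 + #{permutation statistic >= observed}) / (n_perm + 1).
    """
    if len(predicted_ranks) != len(observed_ranks):
        raise OutcomeError("predicted/observed guide count mismatch")
    preds = [list(p) for p in predicted_ranks]
    obs = [list(o) for o in observed_ranks]
    for p, o in zip(preds, obs):
        if len(p) != len(o):
            raise OutcomeError("site count mismatch within a guide")
    if not any(len(p) >= 2 for p in preds):
        raise OutcomeError("need at least one guide with >= 2 sites")
    stat = sum(
        1 for p, o in zip(preds, obs) for a, b in zip(p, o) if a == b
    )
    rng = np.random.default_rng(seed)
    perm_stats = np.zeros(n_perm, dtype=np.int64)
    for p, o in zip(preds, obs):
        # all n_perm within-guide permutations of this guide's observed
        # ranks at once (C-level shuffle along axis 1)
        shuffled = rng.permuted(
            np.tile(np.asarray(o), (n_perm, 1)), axis=1
        )
        perm_stats += (shuffled == np.asarray(p)).sum(axis=1)
    hits = int(np.sum(perm_stats >= stat))
    return stat, (1 + hits) / (n_perm + 1)
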