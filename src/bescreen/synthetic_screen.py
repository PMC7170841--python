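"""Ground-truth simulator for the whole screen.

Generates random yeast-like coding loci, plants per-guide editing rates and
per-outcome fitness effects, and produces pooled-competition read counts:
each guide's cell subpopulation is a mixture of unedited cells (relative
fitness 1) and edited cells (relative fitness 1 - s); subpopulations grow
deterministically and exponentially over a configured number of generations
between the mutagenesis (t0) and end-of-competition (t1) samplings, and
sequencing draws a multinomial of the configured depth per sample.
Synthesis-error guides — one-mismatch variants of designed guides with zero
editing activity — are injected so the downstream null-model machinery can
be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .guide_design import GuideRecord
from .screen_counts import CountTable, make_sample_frame
from .sequence_io import GeneModel, ReferenceSet, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Default study-condition regime: two replicates, editing rates centred on
#: 0.5–0.9, ~3% synthesis-error guides, ten generations of competition and
#: a few hundred reads per guide.
DEFAULT_EDITING_RATE_RANGE = (0.5, 0.9)
DEFAULT_SE_FRACTION = 0.03
DEFAULT_GENERATIONS = 10.0
DEFAULT_DEPTH_PER_GUIDE = 300
DEFAULT_SPECTRUM = {"C>G": 0.45, "C>T": 0.45, "C>A": 0.05, "multi": 0.05}


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Planted ground truth for one simulated screen."""

    editing_rate: dict[str, float]
    fitness_s: dict[str, float]             # selection coefficient of the edit
    spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    se_fraction: float = DEFAULT_SE_FRACTION
    depth_per_guide: int = DEFAULT_DEPTH_PER_GUIDE
    generations: float = DEFAULT_GENERATIONS
    seed: int = 0
    se_parents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum.values()) - 1.0) > 1e-9:
            raise SimulationError("spectrum weights must sum to 1")
        if self.depth_per_guide <= 0:
            raise SimulationError("depth must be positive")
        for gid, r in self.editing_rate.items():
            if not 0.0 <= r <= 1.0:
                raise SimulationError(f"{gid}: editing rate {r} outside [0,1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_codon(rng, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3, p=p))
        if codon not in STOP_CODONS:
            return codon


def generate_reference(
    n_genes: int = 3,
    length_range: tuple[int, int] = (300, 600),
    gc: float = 0.40,
    essential_fraction: float = 0.7,
    seed: int = 0,
    spacer: int = 60,
    chrom: str = "chrI",
) -> ReferenceSet:
    """Random single-chromosome reference with start/stop-flanked CDSs.

    Non-essential genes are split between high_effect (deletion fitness
    0.6) and no_effect (1.0) classes.  Deterministic under ``seed``.
    """
    if n_genes < 1 or length_range[0] < 30 or length_range[0] > length_range[1]:
        raise SimulationError("invalid generator parameters")
    if not 0.0 < gc < 1.0:
        raise SimulationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    parts = ["".join(rng.choice(list("ACGT"), size=spacer, p=p))]
    genes: list[GeneModel] = []
    pos = spacer
    for i in range(n_genes):
        n_codons = int(rng.integers(length_range[0] // 3, length_range[1] // 3 + 1))
        cds = "ATG" + "".join(_random_codon(rng, gc) for _ in range(n_codons - 2))
        cds += str(rng.choice(STOP_CODONS))
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cds if strand == "+" else revcomp(cds)
        if rng.random() < essential_fraction:
            tclass, score = "essential", None
        elif rng.random() < 0.5:
            tclass, score = "high_effect", 0.6
        else:
            tclass, score = "no_effect", 1.0
        genes.append(GeneModel(
            gene_id=f"gene{i:03d}",
            chrom=chrom,
            strand=strand,
            cds_intervals=[(pos, pos + len(cds))],
            target_class=tclass,
            fitness_score=score,
        ))
        parts.append(genomic)
        parts.append("".join(rng.choice(list("ACGT"), size=spacer, p=p)))
        pos += len(cds) + spacer
    ref = ReferenceSet(sequences={chrom: "".join(parts)}, genes=genes)
    ref.validate()
    return ref


def expected_growth_factor(editing_rate: float, s: float, generations: float) -> float:
    """Relative growth of a guide's subpopulation over the competition.

    The unedited fraction grows 2**G-fold, the edited fraction
    2**((1-s)G)-fold; the common 2**G factor cancels in relative abundance,
    so the factor is (1 - r) + r * 2**(-s*G).
    """
    return (1.0 - editing_rate) + editing_rate * 2.0 ** (-s * generations)


def simulate_screen(
    library: list[GuideRecord] | list[str],
    truth: SimTruth,
    replicates: tuple[str, ...] = ("A", "B"),
    abundance_cv: float = 0.5,
) -> tuple[CountTable, pd.Series]:
    """Simulate t0/t1 read counts for both replicates.

    Initial guide abundances are lognormal around a common mean (coefficient
    of variation ``abundance_cv``, mimicking cloning bottlenecks).  SE
    guides listed in ``truth.se_parents`` are added as extra rows named
    ``<parent>_SE`` carrying ``se_fraction``-scaled abundance and no
    editing.  Returns the CountTable and a boolean is_se flag per row.
    """
    ids = [g.guide_id if isinstance(g, GuideRecord) else g for g in library]
    if not ids:
        raise SimulationError("empty library")
    rng = np.random.default_rng(truth.seed)
    sigma = np.sqrt(np.log(1 + abundance_cv**2))
    abund = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(ids))
    rows = list(ids)
    weights = list(abund)
    is_se = [False] * len(ids)
    se_parents = list(truth.se_parents)
    if not se_parents and truth.se_fraction > 0:
        n_se = int(round(truth.se_fraction * len(ids)))
        se_parents = [ids[i] for i in rng.choice(len(ids), size=n_se, replace=False)]
        truth.se_parents = se_parents
    parent_abund = dict(zip(ids, abund))
    for parent in se_parents:
        if parent not in parent_abund:
            raise SimulationError(f"SE parent {parent} not in library")
        # the SE rows model the *abundant* synthesis-error variants kept as
        # controls, so they draw from the same abundance distribution as the
        # designed guides (and sit far above the 0.075 detection ratio)
        rows.append(f"{parent}_SE")
        weights.append(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))
        is_se.append(True)
    weights = np.asarray(weights)
    growth = np.array([
        1.0 if se else expected_growth_factor(
            truth.editing_rate.get(gid, 0.0),
            truth.fitness_s.get(gid, 0.0),
            truth.generations,
        )
        for gid, se in zip(rows, is_se)
    ])
    p0 = weights / weights.sum()
    w1 = weights * growth
    p1 = w1 / w1.sum()
    depth = truth.depth_per_guide * len(rows)
    cols = {}
    for rep in replicates:
        cols[f"T0_mutagenesis:{rep}"] = rng.multinomial(depth, p0)
        cols[f"T_end:{rep}"] = rng.multinomial(depth, p1)
    counts = pd.DataFrame(cols, index=pd.Index(rows, name="guide_id"))
    order = [c for c in counts.columns]
    table = CountTable(counts=counts[order], samples=make_sample_frame(order))
    return table, pd.Series(is_se, index=counts.index, name="is_se")


def simulate_amplicon_genotypes(
    guide: GuideRecord,
    truth: SimTruth,
    n_reads: int = 10000,
    activity_weights: Optional[dict[int, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, int]:
    """Draw edited-read genotypes for one guide's amplicon.

    Edited reads (binomial at the guide's editing rate) are spread over
    single-edit genotypes at each window C (position chosen proportionally
    to activity weight, alt base per the C>G/C>T/C>A spectrum) and, with
    the ``multi`` spectrum weight, over double edits at the top two Cs.
    Returns {genotype key: read count} for edited reads only.
    """
    from .guide_design import DEFAULT_ACTIVITY_WEIGHTS
    from .outcome_model import genotype_key

    rng = rng or np.random.default_rng(truth.seed)
    weights = activity_weights or DEFAULT_ACTIVITY_WEIGHTS
    positions = list(guide.pam_relative_c_positions)
    if not positions:
        raise SimulationError(f"{guide.guide_id}: no editable C")
    rate = truth.editing_rate.get(guide.guide_id, 0.0)
    n_edited = rng.binomial(n_reads, rate)
    if n_edited == 0:
        return {}
    w = np.array([weights.get(p, 0.0) for p in positions], dtype=float)
    if w.sum() == 0:
        w[:] = 1.0
    w /= w.sum()
    alts = ["G", "T", "A"]
    alt_w = np.array([truth.spectrum.get(f"C>{a}", 0.0) for a in alts])
    alt_w = alt_w / alt_w.sum()
    multi_w = truth.spectrum.get("multi", 0.0) if len(positions) >= 2 else 0.0
    out: dict[str, int] = {}
    n_multi = rng.binomial(n_edited, multi_w)
    for _ in range(n_multi):
        top2 = sorted(positions, key=lambda p: -weights.get(p, 0.0))[:2]
        edits = [(p, alts[rng.choice(3, p=alt_w)]) for p in top2]
        key = genotype_key(edits)
        out[key] = out.get(key, 0) + 1
    pos_draw = rng.choice(len(positions), size=n_edited - n_multi, p=w)
    alt_draw = rng.choice(3, size=n_edited - n_multi, p=alt_w)
    for pi, ai in zip(pos_draw, alt_draw):
        key = genotype_key([(positions[pi], alts[ai])])
        out[key] = out.get(key, 0) + 1
    return out


def counts_to_reads(
    table: CountTable,
    sequences: dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[str]]:
    """Expand a count table into shuffled per-sample 20-mer read lists.

    ``sequences`` maps every row id (designed guides and SE variants) to
    its 20-nt variable region.
    """
    rng = rng or np.random.default_rng(0)
    out = {}
    for sample in table.counts.columns:
        reads: list[str] = []
        for gid, n in table.counts[sample].items():
            reads.extend([sequences[gid]] * int(n))
        rng.shuffle(reads)
        out[sample] = reads
    return out
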