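"""Shared builders and independent oracles for the test suite.

Everything here is deliberately written as plain loops over strings so it
stays independent of the package's coordinate machinery.
"""

from __future__ import annotations

from bescreen.guide_design import enumerate_candidates
from bescreen.sequence_io import GeneModel, ReferenceSet, revcomp

HIGH_WEIGHTS = {-18: 1.0, -17: 0.9, -19: 0.8}


def make_site_reference(codon: str, base_idx: int, guide_strand: str):
    """Build a one-gene reference where ``codon[base_idx]`` sits at
    protospacer position -18 of a guide on ``guide_strand``.

    The gene is on the + strand; filler codons are TTT (no C, no G) so the
    focal codon contributes the only candidate editing sites in the window.
    Returns (reference, guide, focal_residue_index_1based).
    """
    pre, post = 8, 14            # filler codons before/after the focal codon
    cds = list("ATG" + "TTT" * pre + codon + "TTT" * post + "TAA")
    start = 30                   # gene start on the chromosome
    res_idx = 1 + pre            # 0-based residue index of the focal codon
    t_in_cds = res_idx * 3 + base_idx
    t = start + t_in_cds         # genomic coordinate of the focal base
    genome = list("AT" * 15) + cds + list("TA" * 15)
    if guide_strand == "+":
        if codon[base_idx] != "C":
            raise ValueError("plus-strand guide needs a C at the focal base")
        pam = t + 18
        genome[pam : pam + 3] = list("AGG")
    else:
        if codon[base_idx] != "G":
            raise ValueError("minus-strand guide needs a template C (coding G)")
        pam = t - 18
        genome[pam - 2 : pam + 1] = list("CCA")
    gene = GeneModel(
        gene_id="focal",
        chrom="chr",
        strand="+",
        cds_intervals=[(start, start + len(cds))],
        target_class="essential",
    )
    ref = ReferenceSet(sequences={"chr": "".join(genome)}, genes=[gene])
    ref.validate()
    cands = [
        c for c in enumerate_candidates(ref)
        if c.pam_genomic_start == pam and c.protospacer_strand == guide_strand
    ]
    assert len(cands) == 1, f"site construction failed for {codon}/{base_idx}"
    return ref, cands[0], res_idx + 1


def _plant(genome: list, pos: int, segment: str) -> None:
    genome[pos : pos + len(segment)] = list(segment)


def build_filter_toy() -> ReferenceSet:
    """Three-gene toy genome with one planted site per design-filter rule."""
    N = 1500
    genome = list(("AT" * N)[:N])

    # gene A: + strand, CDS [100, 400)
    a0 = 100
    # P1 passes: single C at -18 (index 2), PAM AGG
    _plant(genome, a0 + 140, "ATCAGTAGTTAGTGATGTAT" + "AGG")
    # P2 all three high Cs (-19,-18,-17 = idx 1,2,3)
    _plant(genome, a0 + 170, "ACCCGTAGTTAGTGATGTAT" + "TGG")
    # P3 pair -18/-17 (idx 2,3)
    _plant(genome, a0 + 200, "ATCCGTAGTTAGTGATGTAT" + "AGG")
    # P4 BsaI site inside, C at -18
    _plant(genome, a0 + 230, "ATCAGGTCTCAGTGATGTAT" + "AGG")
    # P5 early-CDS C: C at -18 placed at the first CDS base
    #   pam start = cds_start + 18
    _plant(genome, a0 - 2, "GACATTATTATTATTATTAT" + "AGG")  # C lands at a0
    # P6 late-CDS C: single C at -18 lands at CDS position 290 (1-based),
    # fraction 290/300 > 0.75
    _plant(genome, a0 + 289 - 2, "ATCAGTAGTTTGTGATGTTA" + "AGG")
    # P7 duplicated protospacer (in gene A and again intergenic)
    dup = "ATCAGTAGGTTGTGATGTTT"
    _plant(genome, a0 + 60, dup + "AGG")
    _plant(genome, 700, dup + "CGG")
    # P8 NAG-shadowed protospacer
    nag = "ATCTGTAGGTTGTGATGATT"
    _plant(genome, a0 + 30, nag + "AGG")
    _plant(genome, 760, nag + "TAG")

    # gene B: - strand, CDS [900, 1200); plant a - strand site (CCN then
    # 20 bases whose revcomp holds a single high-window C)
    b0 = 900
    seg = "CCA" + revcomp("ATCAGTAGTTAGTGGTGTAT")
    _plant(genome, b0 + 150, seg)
    # gene C: + strand, CDS [1260, 1440), left empty of planted sites
    genes = [
        GeneModel("geneA", "chr", "+", [(100, 400)], "essential"),
        GeneModel("geneB", "chr", "-", [(900, 1200)], "essential"),
        GeneModel("geneC", "chr", "+", [(1260, 1440)], "no_effect", 1.0),
    ]
    ref = ReferenceSet(sequences={"chr": "".join(genome)}, genes=genes)
    ref.validate()
    return ref


def oracle_enumerate(ref: ReferenceSet):
    """Independent re-enumeration of window-overlapping PAM sites.

    Yields (gene, strand, pam_start, protospacer).
    """
    for gene in ref.genes:
        seq = ref.sequences[gene.chrom]

        def in_gene(pos):
            return any(s <= pos < e for s, e in gene.cds_intervals)

        for p in range(20, len(seq) - 2):
            if seq[p + 1 : p + 3] == "GG":
                window = [p - k for k in range(14, 21)]
                if any(in_gene(x) for x in window):
                    yield gene, "+", p, seq[p - 20 : p]
        for q in range(0, len(seq) - 22):
            if seq[q : q + 2] == "CC":
                p = q + 2
                window = [p + k for k in range(14, 21)]
                if any(in_gene(x) for x in window):
                    yield gene, "-", p, revcomp(seq[q + 3 : q + 23])


def oracle_count_sites(ref: ReferenceSet, protospacer: str, pam_tail: str) -> int:
    """Genome-wide occurrences of protospacer + N + ``pam_tail`` (both strands)."""
    total = 0
    rc = revcomp(protospacer)
    left = revcomp(pam_tail)
    for seq in ref.sequences.values():
        for i in range(len(seq) - 22):
            if seq[i : i + 20] == protospacer and seq[i + 21 : i + 23] == pam_tail:
                total += 1
            if seq[i : i + 2] == left and seq[i + 3 : i + 23] == rc:
                total += 1
    return total


def oracle_filter_reasons(ref, gene, strand, pam_start, protospacer,
                          bounds=(0.005, 0.75)) -> list[str]:
    """Independent evaluation of every design rule for one candidate."""
    reasons = []
    idx_c = [i for i, b in enumerate(protospacer) if b == "C"]
    high_idx = [i for i in idx_c if i in (1, 2, 3)]     # -19, -18, -17
    if not high_idx:
        reasons.append("no_high_window_c")
    if {1, 2, 3} <= set(idx_c):
        reasons.append("all_three_high")
    if {2, 3} <= set(idx_c):
        reasons.append("pair_18_17")
    if "GGTCTC" in protospacer or "GAGACC" in protospacer:
        reasons.append("bsai")
    if oracle_count_sites(ref, protospacer, "GG") != 1:
        reasons.append("not_unique")
    if oracle_count_sites(ref, protospacer, "AG") > 0:
        reasons.append("nag_site")
    if gene.target_class in ("essential", "high_effect", "no_effect") and high_idx:
        top = max(high_idx, key=lambda i: HIGH_WEIGHTS[i - 20])
        g_pos = pam_start - (20 - top) if strand == "+" else pam_start + (20 - top)
        cds_idx, off = None, 0
        for s, e in gene.cds_intervals:
            if s <= g_pos < e:
                cds_idx = off + (g_pos - s if gene.strand == "+" else e - 1 - g_pos)
            off += e - s
        if cds_idx is None:
            reasons.append("edit_outside_cds")
        else:
            frac = (cds_idx + 1) / sum(e - s for s, e in gene.cds_intervals)
            if not bounds[0] <= frac <= bounds[1]:
                reasons.append("cds_fraction")
    return reasons
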