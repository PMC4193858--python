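"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

from arraysmith import (
    Candidate,
    GenotypeCall,
    PanelConfig,
    SelectionConfig,
    Tier,
    VariantRecord,
    het_profile,
    tier_of,
)

SMALL_PANEL = PanelConfig(
    diploid_members=("s1", "s2", "s3", "s4"),
    dh_members=("dh1", "dh2"),
)


def make_record(
    panel: PanelConfig,
    chrom: str = "chr01",
    pos: int = 1000,
    ref: str = "A",
    alts: tuple[str, ...] = ("G",),
    qual: float = 50.0,
    depth: int = 30,
    genotypes: dict | None = None,
    depths: dict | None = None,
    annotations: dict | None = None,
    combined_depth: int | None = None,
    snp_id: str = "",
) -> VariantRecord:
    """Record with hom-ref calls everywhere unless overridden per sample."""
    genotypes = genotypes or {}
    depths = depths or {}
    per_sample = {
        s: GenotypeCall(genotypes.get(s, (0, 0)), depths.get(s, depth))
        for s in panel.all_samples
    }
    if combined_depth is None:
        combined_depth = sum(c.depth for c in per_sample.values())
    return VariantRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=alts,
        site_quality=qual, combined_depth=combined_depth,
        per_sample=per_sample, annotations=annotations or {}, snp_id=snp_id,
    )


def make_candidate(
    panel: PanelConfig,
    pos: int,
    het_members: tuple[int, ...],
    hom_alt_members: tuple[int, ...] = (),
    score: float | None = None,
    chrom: str = "chr01",
    snp_id: str = "",
) -> Candidate:
    """Candidate with a specified heterozygosity pattern over diploid members."""
    genotypes = {}
    for i, s in enumerate(panel.diploid_members):
        if i in het_members:
            genotypes[s] = (0, 1)
        elif i in hom_alt_members:
            genotypes[s] = (1, 1)
        else:
            genotypes[s] = (0, 0)
    rec = make_record(panel, chrom=chrom, pos=pos, genotypes=genotypes, snp_id=snp_id)
    profile = het_profile(rec, panel)
    return Candidate(rec, profile, score, tier_of(profile))


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_kmer_count(sequences: dict[str, str], kmer: str) -> int:
    """Occurrences of ``kmer`` on either strand, counted per genome window.

    A window matches when its forward sequence equals the k-mer or its
    reverse complement (each window counted once, overlaps allowed), which
    is the both-strand scan the canonical index must reproduce.
    """
    targets = {kmer}
    targets.add(revcomp(kmer))
    total = 0
    for seq in sequences.values():
        for target in targets:
            start = 0
            while True:
                i = seq.find(target, start)
                if i == -1:
                    break
                total += 1
                start = i + 1
    if revcomp(kmer) == kmer:
        total //= 2  # palindromic: both strand scans see the same windows
    return total


def oracle_best_coverage(
    cands: list[Candidate],
    panel: PanelConfig,
    config: SelectionConfig | None = None,
) -> int:
    """Exhaustive-search optimum of distinct-member coverage.

    Enumerates every subset of the budget size that respects the tier-1 cap
    and the one-single-member-SNP-per-member rule, and returns the maximum
    number of distinct heterozygous members covered.
    """
    config = config or SelectionConfig()
    n = min(config.max_per_fp, len(cands))
    best = -1
    for combo in combinations(cands, n):
        if sum(1 for c in combo if c.tier is Tier.TIER1) > config.max_tier1:
            continue
        t3 = [c.profile.het_vector.index(True) for c in combo if c.tier is Tier.TIER3]
        if len(t3) != len(set(t3)):
            continue
        cov = len({
            m for c in combo for m, h in enumerate(c.profile.het_vector) if h
        })
        best = max(best, cov)
    return best


def coverage_of(cands: list[Candidate]) -> int:
    return len({m for c in cands for m, h in enumerate(c.profile.het_vector) if h})
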