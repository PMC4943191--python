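"""Within-species synonymous/non-synonymous nucleotide diversity.

Site counting and difference classification follow the Nei & Gojobori (1986)
counting scheme: fractional synonymous site counts per codon, and equal-weight
averaging over all mutational pathways between differing codons, excluding
pathways that pass through a stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

from .seq_io import CodonAlignment, genetic_code_table

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityStats",
    "count_sites",
    "classify_pair_diffs",
    "diversity_stats",
    "aggregate_species",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class DiversityStats:
    """Per-species diversity summary.

    ``pi_S`` and ``pi_N`` are per-synonymous-site and per-non-synonymous-site
    pairwise diversities; ``syn_sites``/``nonsyn_sites`` are fractional
    Nei-Gojobori site counts averaged over sequences.
    """

    n_sequences: int
    pi_total: float
    pi_S: float
    pi_N: float
    syn_sites: float
    nonsyn_sites: float
    n_syn_poly: float
    n_nonsyn_poly: float


@lru_cache(maxsize=None)
def count_sites(codon: str, genetic_code: str = "standard") -> tuple[float, float]:
    """Fractional (synonymous, non-synonymous) site counts for a sense codon.

    At each of the three positions, the synonymous fraction is the number of
    single-nucleotide mutants that are synonymous and non-stop divided by the
    number of non-stop mutants; the two site counts always sum to 3.
    """
    code = genetic_code_table(genetic_code)
    if code.is_stop(codon):
        raise ValueError(f"cannot count sites for stop codon {codon!r}")
    aa = code.translate(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            n_valid += 1
            if code.translate(mutant) == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def classify_pair_diffs(
    codon_a: str, codon_b: str, genetic_code: str = "standard"
) -> tuple[float, float] | None:
    """Average (synonymous, non-synonymous) step counts between two codons.

    Enumerates every ordering of the differing positions, drops orderings that
    pass through a stop codon, and averages the per-step classification over
    the remainder.  Returns ``None`` when every pathway is stop-blocked.
    """
    code = genetic_code_table(genetic_code)
    if code.is_stop(codon_a) or code.is_stop(codon_b):
        raise ValueError(f"stop codon in pair ({codon_a!r}, {codon_b!r})")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        syn = 0
        nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.translate(nxt) == code.translate(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if blocked:
            continue
        syn_total += syn
        nonsyn_total += nonsyn
        n_paths += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, nonsyn_total / n_paths


def _sequence_site_counts(
    residues: str, codons: tuple[int, ...], genetic_code: str
) -> tuple[float, float]:
    syn = 0.0
    nonsyn = 0.0
    for i in codons:
        s, n = count_sites(residues[3 * i : 3 * i + 3], genetic_code)
        syn += s
        nonsyn += n
    return syn, nonsyn


def diversity_stats(alignment: CodonAlignment) -> DiversityStats:
    """Compute pairwise diversity statistics for one species alignment.

    pi_S is the mean over unordered sequence pairs of pathway-classified
    synonymous differences divided by the mean per-sequence synonymous site
    count; pi_N analogously.  pi_total is the mean pairwise nucleotide
    difference per unmasked nucleotide.
    """
    if alignment.n_sequences < 2:
        raise ValueError("diversity requires at least 2 sequences")
    code = alignment.genetic_code
    codons = alignment.unmasked_codons
    n_seq = alignment.n_sequences
    rows = [res for _, res in alignment.sequences]

    syn_sites_sum = 0.0
    nonsyn_sites_sum = 0.0
    for res in rows:
        s, n = _sequence_site_counts(res, codons, code)
        syn_sites_sum += s
        nonsyn_sites_sum += n
    syn_sites = syn_sites_sum / n_seq
    nonsyn_sites = nonsyn_sites_sum / n_seq

    # Only codon columns that vary contribute to any pair difference.
    variable = [
        i for i in codons if len({res[3 * i : 3 * i + 3] for res in rows}) > 1
    ]

    pair_syn = 0.0
    pair_nonsyn = 0.0
    pair_nt = 0
    n_pairs = 0
    for a, b in combinations(range(n_seq), 2):
        n_pairs += 1
        for i in variable:
            ca = rows[a][3 * i : 3 * i + 3]
            cb = rows[b][3 * i : 3 * i + 3]
            if ca == cb:
                continue
            pair_nt += sum(1 for x, y in zip(ca, cb) if x != y)
            cls = classify_pair_diffs(ca, cb, code)
            if cls is None:
                logger.warning(
                    "codon pair (%s, %s) has no stop-free pathway; skipped", ca, cb
                )
                continue
            pair_syn += cls[0]
            pair_nonsyn += cls[1]

    total_nt = 3 * len(codons)
    pi_total = (pair_nt / n_pairs / total_nt) if total_nt else 0.0
    pi_S = (pair_syn / n_pairs / syn_sites) if syn_sites > 0 else 0.0
    pi_N = (pair_nonsyn / n_pairs / nonsyn_sites) if nonsyn_sites > 0 else 0.0

    # Segregating codon changes: classify each distinct variant against the
    # majority codon of the column (ties broken lexicographically so the
    # counts are invariant under sequence reordering).
    n_syn_poly = 0.0
    n_nonsyn_poly = 0.0
    for i in variable:
        column = [res[3 * i : 3 * i + 3] for res in rows]
        counts: dict[str, int] = {}
        for c in column:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        consensus = min(c for c in counts if counts[c] == best)
        for variant in dict.fromkeys(column):
            if variant == consensus:
                continue
            cls = classify_pair_diffs(consensus, variant, code)
            if cls is None:
                continue
            n_syn_poly += cls[0]
            n_nonsyn_poly += cls[1]

    return DiversityStats(
        n_sequences=n_seq,
        pi_total=pi_total,
        pi_S=pi_S,
        pi_N=pi_N,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        n_syn_poly=n_syn_poly,
        n_nonsyn_poly=n_nonsyn_poly,
    )


def aggregate_species(stats: list[DiversityStats]) -> DiversityStats:
    """Unweighted arithmetic mean of each statistic across species (or loci)."""
    if not stats:
        raise ValueError("cannot aggregate an empty list of DiversityStats")
    if len(stats) == 1:
        return stats[0]
    k = len(stats)

    def mean(attr: str) -> float:
        return sum(getattr(s, attr) for s in stats) / k

    return DiversityStats(
        n_sequences=round(mean("n_sequences")),
        pi_total=mean("pi_total"),
        pi_S=mean("pi_S"),
        pi_N=mean("pi_N"),
        syn_sites=mean("syn_sites"),
        nonsyn_sites=mean("nonsyn_sites"),
        n_syn_poly=mean("n_syn_poly"),
        n_nonsyn_poly=mean("n_nonsyn_poly"),
    )
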