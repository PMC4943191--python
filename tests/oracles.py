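"""Independent brute-force oracles used to validate the package's estimators.

These deliberately re-derive every quantity from first principles (full
enumeration, no shared code paths with the package beyond the NCBI code
tables) so that implementation and oracle stay on separate routes.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np
from Bio.Data import CodonTable

_BASES = "ACGT"
_TABLE_IDS = {
    "standard": 1,
    "vertebrate-mitochondrial": 2,
    "invertebrate-mitochondrial": 5,
    "plant-plastid": 11,
}


def _table(code_name: str):
    return CodonTable.unambiguous_dna_by_id[_TABLE_IDS[code_name]]


def sense_codons(code_name: str) -> list[str]:
    table = _table(code_name)
    return [
        "".join(c)
        for c in product(_BASES, repeat=3)
        if "".join(c) not in table.stop_codons
    ]


def _aa(codon: str, table) -> str:
    return "*" if codon in table.stop_codons else table.forward_table[codon]


def brute_site_counts(codon: str, code_name: str = "standard") -> tuple[float, float]:
    """Brute-force fractional site counts over all 9 single-nt mutants."""
    table = _table(code_name)
    aa = _aa(codon, table)
    syn = 0.0
    for pos in range(3):
        mutants = [
            codon[:pos] + b + codon[pos + 1 :] for b in _BASES if b != codon[pos]
        ]
        valid = [m for m in mutants if m not in table.stop_codons]
        if valid:
            syn += sum(1 for m in valid if _aa(m, table) == aa) / len(valid)
    return syn, 3.0 - syn


def brute_pathway(
    codon_a: str, codon_b: str, code_name: str = "standard"
) -> tuple[float, float] | None:
    """Pathway-averaged (syn, nonsyn) steps via explicit permutation listing."""
    table = _table(code_name)
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return (0.0, 0.0)
    outcomes = []
    for order in permutations(positions):
        steps = []
        state = codon_a
        valid = True
        for pos in order:
            nxt = state[:pos] + codon_b[pos] + state[pos + 1 :]
            if nxt in table.stop_codons:
                valid = False
                break
            steps.append(1 if _aa(nxt, table) == _aa(state, table) else 0)
            state = nxt
        if valid:
            outcomes.append(steps)
    if not outcomes:
        return None
    syn = float(np.mean([sum(s) for s in outcomes]))
    return syn, len(positions) - syn


def brute_parsimony_triplet(
    ci: str, cm: str, co: str, code_name: str = "standard"
) -> tuple[tuple[float, float], ...] | None:
    """Exhaustive ancestral enumeration over every sense codon.

    Returns tie-averaged ((syn, nonsyn) island, mainland, outgroup) branch
    changes, or ``None`` when all minimal reconstructions are stop-blocked.
    """
    tips = (ci, cm, co)
    best_cost = None
    minimal = []
    for anc in sense_codons(code_name):
        cost = sum(
            sum(1 for x, y in zip(anc, tip) if x != y) for tip in tips
        )
        if best_cost is None or cost < best_cost:
            best_cost = cost
            minimal = [anc]
        elif cost == best_cost:
            minimal.append(anc)
    usable = []
    for anc in minimal:
        branch_cls = [brute_pathway(anc, tip, code_name) for tip in tips]
        if all(c is not None for c in branch_cls):
            usable.append(branch_cls)
    if not usable:
        return None
    out = []
    for k in range(3):
        out.append(
            (
                float(np.mean([u[k][0] for u in usable])),
                float(np.mean([u[k][1] for u in usable])),
            )
        )
    return tuple(out)


def brute_diversity(rows: list[str], code_name: str = "standard"):
    """Exhaustive pairwise diversity for a small, gap-free codon alignment.

    Returns (pi_total, pi_S, pi_N) using brute-force site counting and
    pathway classification for every sequence pair and codon.
    """
    n = len(rows)
    n_codons = len(rows[0]) // 3
    site_syn = []
    for res in rows:
        site_syn.append(
            sum(
                brute_site_counts(res[3 * i : 3 * i + 3], code_name)[0]
                for i in range(n_codons)
            )
        )
    mean_syn = float(np.mean(site_syn))
    mean_nonsyn = 3.0 * n_codons - mean_syn

    pair_syn = pair_nonsyn = pair_nt = 0.0
    n_pairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            n_pairs += 1
            for i in range(n_codons):
                ca = rows[a][3 * i : 3 * i + 3]
                cb = rows[b][3 * i : 3 * i + 3]
                pair_nt += sum(1 for x, y in zip(ca, cb) if x != y)
                cls = brute_pathway(ca, cb, code_name)
                if cls is not None:
                    pair_syn += cls[0]
                    pair_nonsyn += cls[1]
    pi_total = pair_nt / n_pairs / (3 * n_codons)
    pi_s = pair_syn / n_pairs / mean_syn if mean_syn else 0.0
    pi_n = pair_nonsyn / n_pairs / mean_nonsyn if mean_nonsyn else 0.0
    return pi_total, pi_s, pi_n


def brute_wilcoxon(values, center: float, tail: str) -> float:
    """Exact signed-rank P value by listing all 2^m sign assignments."""
    diffs = [v - center for v in values if v != center]
    m = len(diffs)
    assert m >= 1
    absd = sorted((abs(d), i) for i, d in enumerate(diffs))
    ranks = [0.0] * m
    j = 0
    while j < m:
        k = j
        while k + 1 < m and absd[k + 1][0] == absd[j][0]:
            k += 1
        mid = (j + k) / 2 + 1
        for t in range(j, k + 1):
            ranks[absd[t][1]] = mid
        j = k + 1
    w_obs = sum(r for d, r in zip(diffs, ranks) if d > 0)
    n_ge = n_le = 0
    total = 2**m
    for signs in product((0, 1), repeat=m):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            n_ge += 1
        if w <= w_obs + 1e-12:
            n_le += 1
    p_greater = n_ge / total
    p_less = n_le / total
    if tail == "greater":
        return min(1.0, p_greater)
    if tail == "less":
        return min(1.0, p_less)
    return min(1.0, 2 * min(p_greater, p_less))


def brute_spearman(x, y) -> float:
    """Spearman rho via explicit mid-ranks and the Pearson formula on ranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        j = 0
        while j < len(v):
            k = j
            while k + 1 < len(v) and v[order[k + 1]] == v[order[j]]:
                k += 1
            mid = (j + k) / 2 + 1
            for t in range(j, k + 1):
                ranks[order[t]] = mid
            j = k + 1
        return ranks

    rx = midranks(list(x))
    ry = midranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
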