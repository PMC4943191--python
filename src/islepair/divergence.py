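"""Lineage-specific dN, dS and omega from island/mainland/outgroup triplets.

Branch substitutions are assigned by parsimony over the single internal node
of the unrooted triplet: for each codon pattern, every sense codon buildable
from the observed bases is considered as the ancestral state, minimal-change
ancestors are retained, and per-branch changes (classified syn/non-syn by
pathway averaging) are averaged over ties.  Proportions are corrected with the
Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).

This is a deliberate counting-based substitute for maximum-likelihood branch
models; outputs carry a ``method`` tag saying so.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

from .diversity import classify_pair_diffs, count_sites
from .seq_io import CodonAlignment, genetic_code_table

logger = logging.getLogger(__name__)

__all__ = [
    "LineageSubstitution",
    "SaturationError",
    "BRANCHES",
    "METHOD_TAG",
    "assign_lineage_changes",
    "branch_rates",
    "jukes_cantor",
    "representative_sequence",
    "triplet_substitutions",
    "comparison_divergence",
]

BRANCHES = ("island", "mainland", "outgroup")
METHOD_TAG = "parsimony+NG86-counting+JC69 (substitute for ML branch models)"

SATURATION_WARN = 0.6
SATURATION_ERROR = 0.75


class SaturationError(ValueError):
    """Raised when a branch proportion reaches the Jukes-Cantor singularity."""


@dataclass(frozen=True)
class LineageSubstitution:
    """Substitution statistics for one branch of a comparison triplet."""

    branch: str
    syn_changes: float
    nonsyn_changes: float
    syn_sites: float
    nonsyn_sites: float
    dS: float
    dN: float
    omega: float | None  # None when dS == 0 (flagged undefined, never 0)
    flags: tuple[str, ...] = ()


@lru_cache(maxsize=None)
def _codon_pattern_changes(
    ci: str, cm: str, co: str, genetic_code: str
) -> tuple[tuple[float, float], ...] | None:
    """Per-branch (syn, nonsyn) changes for one codon pattern, tie-averaged.

    Every sense codon of the genetic code is considered as the ancestral
    state; minimal-total-change ancestors are kept and branch classifications
    averaged over them.  Returns ``None`` when every minimal reconstruction
    leaves some branch with only stop-blocked pathways.
    """
    code = genetic_code_table(genetic_code)
    tips = (ci, cm, co)
    if all(t == ci for t in tips):
        return ((0.0, 0.0),) * 3
    candidates = code.sense_codons
    costs = {
        anc: sum(sum(1 for x, y in zip(anc, t) if x != y) for t in tips)
        for anc in candidates
    }
    best = min(costs.values())
    minimal = [anc for anc in candidates if costs[anc] == best]

    totals = [[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]]
    n_used = 0
    for anc in minimal:
        per_branch = []
        ok = True
        for t in tips:
            cls = classify_pair_diffs(anc, t, genetic_code)
            if cls is None:
                ok = False
                break
            per_branch.append(cls)
        if not ok:
            continue
        n_used += 1
        for k in range(3):
            totals[k][0] += per_branch[k][0]
            totals[k][1] += per_branch[k][1]
    if n_used == 0:
        return None
    return tuple((t[0] / n_used, t[1] / n_used) for t in totals)


def assign_lineage_changes(triplet: CodonAlignment) -> dict[str, tuple[float, float]]:
    """Raw (syn, nonsyn) change counts per branch for a 3-sequence alignment.

    Sequence order is interpreted as (island, mainland, outgroup).
    """
    if triplet.n_sequences != 3:
        raise ValueError(f"triplet must have exactly 3 sequences, got {triplet.n_sequences}")
    codons = triplet.unmasked_codons
    if not codons:
        raise ValueError("triplet alignment is fully masked")
    rows = [res for _, res in triplet.sequences]
    totals = {b: [0.0, 0.0] for b in BRANCHES}
    for i in codons:
        lo, hi = 3 * i, 3 * i + 3
        per_branch = _codon_pattern_changes(
            rows[0][lo:hi], rows[1][lo:hi], rows[2][lo:hi], triplet.genetic_code
        )
        if per_branch is None:
            logger.warning("codon %d has no stop-free reconstruction; skipped", i + 1)
            continue
        for branch, (syn, nonsyn) in zip(BRANCHES, per_branch):
            totals[branch][0] += syn
            totals[branch][1] += nonsyn
    return {b: (v[0], v[1]) for b, v in totals.items()}


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); requires p < 3/4."""
    if p < 0:
        raise ValueError(f"proportion must be nonnegative, got {p}")
    if p >= SATURATION_ERROR:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: distance undefined")
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def branch_rates(
    branch: str,
    syn_changes: float,
    nonsyn_changes: float,
    syn_sites: float,
    nonsyn_sites: float,
) -> LineageSubstitution:
    """Convert raw branch counts into JC-corrected dS, dN and omega."""
    if syn_sites <= 0 or nonsyn_sites <= 0:
        raise ValueError("site counts must be positive")
    p_S = syn_changes / syn_sites
    p_N = nonsyn_changes / nonsyn_sites
    flags = []
    for label, p in (("p_S", p_S), ("p_N", p_N)):
        if SATURATION_WARN <= p < SATURATION_ERROR:
            flags.append(f"{label}_near_saturation")
            logger.warning("%s branch %s = %.3f approaching JC saturation", branch, label, p)
    dS = jukes_cantor(p_S)
    dN = jukes_cantor(p_N)
    if dS == 0.0:
        omega = None
        flags.append("omega_undefined_dS_zero")
    else:
        omega = dN / dS
    return LineageSubstitution(
        branch=branch,
        syn_changes=syn_changes,
        nonsyn_changes=nonsyn_changes,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        dS=dS,
        dN=dN,
        omega=omega,
        flags=tuple(flags),
    )


def representative_sequence(alignment: CodonAlignment) -> str:
    """Majority-rule consensus per column; ties go to the first sequence."""
    if alignment.n_sequences == 0:
        raise ValueError("empty alignment")
    rows = [res for _, res in alignment.sequences]
    if len(rows) == 1:
        return rows[0]
    out = []
    for col in range(alignment.length_nt):
        column = [r[col] for r in rows]
        counts: dict[str, int] = {}
        for b in column:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        winners = [b for b, c in counts.items() if c == best]
        if len(winners) > 1:
            pick = column[0]
            logger.debug("consensus tie at column %d among %s; using %r", col, winners, pick)
        else:
            pick = winners[0]
        out.append(pick)
    return "".join(out)


def _mean_site_counts(triplet: CodonAlignment) -> tuple[float, float]:
    codons = triplet.unmasked_codons
    syn = 0.0
    nonsyn = 0.0
    for _, res in triplet.sequences:
        for i in codons:
            s, n = count_sites(res[3 * i : 3 * i + 3], triplet.genetic_code)
            syn += s
            nonsyn += n
    k = triplet.n_sequences
    return syn / k, nonsyn / k


def triplet_substitutions(triplet: CodonAlignment) -> dict[str, LineageSubstitution]:
    """Full per-branch LineageSubstitution set for one 3-sequence alignment.

    Site denominators are the mean fractional site counts over the three
    sequences, shared by all branches.
    """
    raw = assign_lineage_changes(triplet)
    syn_sites, nonsyn_sites = _mean_site_counts(triplet)
    return {
        b: branch_rates(b, raw[b][0], raw[b][1], syn_sites, nonsyn_sites)
        for b in BRANCHES
    }


def _average_branch(subs: list[LineageSubstitution], branch: str) -> LineageSubstitution:
    """Average dN and dS (and raw counts) separately; omega = mean dN / mean dS."""
    k = len(subs)
    dS = sum(s.dS for s in subs) / k
    dN = sum(s.dN for s in subs) / k
    flags = tuple(sorted({f for s in subs for f in s.flags}))
    if dS == 0.0:
        omega = None
        if "omega_undefined_dS_zero" not in flags:
            flags = flags + ("omega_undefined_dS_zero",)
    else:
        omega = dN / dS
    return LineageSubstitution(
        branch=branch,
        syn_changes=sum(s.syn_changes for s in subs) / k,
        nonsyn_changes=sum(s.nonsyn_changes for s in subs) / k,
        syn_sites=sum(s.syn_sites for s in subs) / k,
        nonsyn_sites=sum(s.nonsyn_sites for s in subs) / k,
        dS=dS,
        dN=dN,
        omega=omega,
        flags=flags,
    )


def comparison_divergence(
    alignment: CodonAlignment,
    island_ids: list[str],
    mainland_ids: list[str],
    outgroup_id: str,
    mode: str = "average",
) -> dict[str, LineageSubstitution]:
    """Branch statistics for a comparison with possibly multiple species per clade.

    mode="average" (default): each island species forms a triplet with the
    mainland-clade consensus and the outgroup, and the island branch values
    are averaged across species (dN and dS averaged separately); symmetrically
    for mainland.  The outgroup branch comes from the consensus-vs-consensus
    triplet.  mode="consensus": a single consensus triplet throughout.
    """
    if mode not in ("average", "consensus"):
        raise ValueError(f"unknown mode {mode!r}")

    def triplet_for(i_seq: tuple[str, str], m_seq: tuple[str, str]) -> CodonAlignment:
        return CodonAlignment(
            sequences=(i_seq, m_seq, (outgroup_id, alignment.sequence(outgroup_id))),
            genome=alignment.genome,
            genetic_code=alignment.genetic_code,
            masked=alignment.masked,
        )

    island_cons = representative_sequence(alignment.subset(list(island_ids)))
    mainland_cons = representative_sequence(alignment.subset(list(mainland_ids)))
    cons_triplet = triplet_for(("island", island_cons), ("mainland", mainland_cons))

    if mode == "consensus" or (len(island_ids) == 1 and len(mainland_ids) == 1):
        return triplet_substitutions(cons_triplet)

    island_subs = [
        triplet_substitutions(
            triplet_for((sid, alignment.sequence(sid)), ("mainland", mainland_cons))
        )["island"]
        for sid in island_ids
    ]
    mainland_subs = [
        triplet_substitutions(
            triplet_for(("island", island_cons), (sid, alignment.sequence(sid)))
        )["mainland"]
        for sid in mainland_ids
    ]
    outgroup_sub = triplet_substitutions(cons_triplet)["outgroup"]
    return {
        "island": _average_branch(island_subs, "island"),
        "mainland": _average_branch(mainland_subs, "mainland"),
        "outgroup": outgroup_sub,
    }
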