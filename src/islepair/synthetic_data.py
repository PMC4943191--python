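"""Synthetic island/mainland/outgroup codon datasets with known truth.

A haploid structured coalescent (time in units of 2N generations, pairwise
coalescence rate 1) generates genealogies for an island and a mainland sample;
the island deme is founded from the mainland at ``split_time``, optionally
through a founder bottleneck that instantaneously reduces the island ancestry
to ``bottleneck_founders`` lineages.  A single outgroup lineage attaches at
``outgroup_time``.

Mutations are Poisson with rate theta/2 per nucleotide site per unit time and
are applied to explicit codon sequences (finite sites, so multi-hit codons
exercise the pathway-averaging machinery).  The mutant base is drawn uniformly
from the non-stop alternatives at the hit position, so stop codons never
arise and the per-position synonymous fraction equals the fractional site
counting used by the estimators; synonymous mutations are always accepted and
non-synonymous mutations are accepted with probability
``nonsyn_neutral_fraction`` (and, on the divergence era of the genealogy,
``nonsyn_div_fraction`` when set), emulating strong purifying selection by
rejection.  Under neutrality E[pi] = theta per site.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .seq_io import (
    CodonAlignment,
    ComparisonManifest,
    genetic_code_table,
    write_codon_alignment,
    write_manifest,
)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioParams", "simulate_comparison", "simulate_dataset"]


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of one simulated island-mainland comparison."""

    n_codons: int = 100
    #: population-scaled mutation rate per nucleotide site (2N*mu, haploid).
    theta: float = 0.01
    #: island-mainland split, units of 2N generations before present.
    split_time: float = 1.0
    #: lineages surviving the founding event; ``None`` disables the bottleneck.
    bottleneck_founders: int | None = None
    #: (island, mainland) chromosomes sampled.
    sample_sizes: tuple[int, int] = (5, 5)
    #: outgroup divergence, units of 2N generations (should dwarf theta scale).
    outgroup_time: float = 10.0
    #: acceptance probability for non-synonymous mutations (1 = neutral).
    nonsyn_neutral_fraction: float = 1.0
    #: acceptance probability for non-synonymous mutations older than the
    #: split (divergence era); defaults to ``nonsyn_neutral_fraction``.
    nonsyn_div_fraction: float | None = None
    #: island<->mainland lineage migration rate before the split (per lineage).
    migration_rate: float = 0.0
    seed: int = 0
    genetic_code: str = "standard"
    genome: str = "mitochondrial"
    taxon_group: str = "bird"
    direction: str = "mainland_to_island"

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.theta < 0 or self.split_time < 0 or self.outgroup_time < 0:
            raise ValueError("rates and times must be nonnegative")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be nonnegative")
        if not 0 <= self.nonsyn_neutral_fraction <= 1:
            raise ValueError("nonsyn_neutral_fraction must be in [0, 1]")
        if self.nonsyn_div_fraction is not None and not 0 <= self.nonsyn_div_fraction <= 1:
            raise ValueError("nonsyn_div_fraction must be in [0, 1]")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        if self.bottleneck_founders is not None and self.bottleneck_founders < 1:
            raise ValueError("bottleneck_founders must be >= 1")


class _Node:
    __slots__ = ("id", "time", "children", "parent")

    def __init__(self, node_id: int, time: float):
        self.id = node_id
        self.time = time
        self.children: list[_Node] = []
        self.parent: _Node | None = None


def _merge(a: _Node, b: _Node, time: float, counter: list[int]) -> _Node:
    counter[0] += 1
    parent = _Node(counter[0], time)
    parent.children = [a, b]
    a.parent = parent
    b.parent = parent
    return parent


def _simulate_genealogy(params: ScenarioParams, rng):
    """Return (root, island_tips, mainland_tips, outgroup_tip, truth dict)."""
    n_isl, n_main = params.sample_sizes
    counter = [0]

    def tip() -> _Node:
        counter[0] += 1
        return _Node(counter[0], 0.0)

    island = [tip() for _ in range(n_isl)]
    mainland = [tip() for _ in range(n_main)]
    island_tips, mainland_tips = list(island), list(mainland)

    # Phase 1: two demes until the split, with optional lineage migration.
    t = 0.0
    while t < params.split_time and (len(island) + len(mainland)) > 1:
        ki, km = len(island), len(mainland)
        c_rate = ki * (ki - 1) / 2.0 + km * (km - 1) / 2.0
        m_rate = params.migration_rate * (ki + km)
        total = c_rate + m_rate
        if total == 0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= params.split_time:
            break
        t = t_next
        if rng.random() < c_rate / total:
            # coalescence, deme chosen proportional to its pair count
            pi = ki * (ki - 1) / 2.0
            pool = island if rng.random() < pi / c_rate else mainland
            k = len(pool)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = pool[i], pool[j]
            pool[:] = [n for idx, n in enumerate(pool) if idx not in (i, j)]
            pool.append(_merge(a, b, t, counter))
        else:
            if rng.random() < ki / (ki + km) and ki > 0:
                island_idx = rng.integers(ki)
                mainland.append(island.pop(island_idx))
            elif km > 0:
                mainland_idx = rng.integers(km)
                island.append(mainland.pop(mainland_idx))

    # Founding event: instantaneous bottleneck of the island ancestry.
    t = params.split_time
    if params.bottleneck_founders is not None:
        while len(island) > params.bottleneck_founders:
            k = len(island)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = island[i], island[j]
            island[:] = [n for idx, n in enumerate(island) if idx not in (i, j)]
            island.append(_merge(a, b, t, counter))

    # Phase 2: ancestral (mainland) population back to the ingroup MRCA.
    pool = island + mainland
    while len(pool) > 1:
        k = len(pool)
        rate = k * (k - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = pool[i], pool[j]
        pool[:] = [n for idx, n in enumerate(pool) if idx not in (i, j)]
        pool.append(_merge(a, b, t, counter))
    ingroup_mrca = pool[0]
    t_mrca = ingroup_mrca.time

    outgroup_tip = tip()
    root_time = params.outgroup_time
    if t_mrca >= params.outgroup_time:
        logger.warning(
            "ingroup MRCA (%.3f) predates outgroup_time (%.3f); rooting above it",
            t_mrca,
            params.outgroup_time,
        )
        root_time = t_mrca
    root = _merge(ingroup_mrca, outgroup_tip, root_time, counter)

    # Divergence-era branch lengths for the representative triplet
    # (first island tip, first mainland tip, outgroup).
    t_pair = _tmrca(island_tips[0], mainland_tips[0])
    truth = {
        "t_ingroup_mrca": t_mrca,
        "t_root": root_time,
        "t_representative_pair": t_pair,
        "expected_pi_per_site_neutral": params.theta,
        "expected_branch_subs_per_site": {
            "island": params.theta / 2.0 * t_pair,
            "mainland": params.theta / 2.0 * t_pair,
            "outgroup": params.theta / 2.0 * (2.0 * root_time - t_pair),
        },
    }
    return root, island_tips, mainland_tips, outgroup_tip, truth


def _tmrca(a: _Node, b: _Node) -> float:
    ancestors = {}
    node = a
    while node is not None:
        ancestors[node.id] = node.time
        node = node.parent
    node = b
    while node is not None:
        if node.id in ancestors:
            return node.time
        node = node.parent
    raise RuntimeError("disconnected genealogy")


def _mutate_sequences(root: _Node, params: ScenarioParams, rng) -> dict[int, str]:
    """Drop mutations on every branch; return tip-id -> sequence."""
    code = genetic_code_table(params.genetic_code)
    sense = code.sense_codons
    root_seq = list("".join(rng.choice(sense) for _ in range(params.n_codons)))
    length_nt = 3 * params.n_codons
    rate_per_time = params.theta / 2.0 * length_nt
    div_fraction = (
        params.nonsyn_div_fraction
        if params.nonsyn_div_fraction is not None
        else params.nonsyn_neutral_fraction
    )
    bases = "ACGT"
    out: dict[int, str] = {}

    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if not node.children:
            out[node.id] = "".join(seq)
            continue
        for child in node.children:
            branch = node.time - child.time
            child_seq = list(seq)
            n_mut = rng.poisson(rate_per_time * branch)
            for _ in range(n_mut):
                pos = int(rng.integers(length_nt))
                old = child_seq[pos]
                ci = pos // 3
                codon = child_seq[3 * ci] + child_seq[3 * ci + 1] + child_seq[3 * ci + 2]
                # mutant base uniform over non-stop alternatives at this position
                options = []
                for base in bases:
                    if base == old:
                        continue
                    cand = codon[: pos % 3] + base + codon[pos % 3 + 1 :]
                    if not code.is_stop(cand):
                        options.append((base, cand))
                if not options:
                    continue
                new, mutant = options[int(rng.integers(len(options)))]
                if code.translate(mutant) != code.translate(codon):
                    t_mut = child.time + rng.random() * branch
                    accept = (
                        div_fraction
                        if t_mut >= params.split_time
                        else params.nonsyn_neutral_fraction
                    )
                    if rng.random() >= accept:
                        continue
                child_seq[pos] = new
            stack.append((child, child_seq))
    return out


def simulate_comparison(params: ScenarioParams, rng=None):
    """Simulate one comparison.

    Returns ``(island_alignment, mainland_alignment, triplet_alignment,
    truth)`` where the triplet holds the first island sample, first mainland
    sample and the outgroup sequence (ids ``island``, ``mainland``,
    ``outgroup``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    root, island_tips, mainland_tips, outgroup_tip, truth = _simulate_genealogy(
        params, rng
    )
    seqs = _mutate_sequences(root, params, rng)

    def alignment(pairs) -> CodonAlignment:
        return CodonAlignment(
            sequences=tuple(pairs),
            genome=params.genome,
            genetic_code=params.genetic_code,
        )

    island_aln = alignment(
        (f"isl_{i + 1}", seqs[tip.id]) for i, tip in enumerate(island_tips)
    )
    mainland_aln = alignment(
        (f"main_{i + 1}", seqs[tip.id]) for i, tip in enumerate(mainland_tips)
    )
    triplet = alignment(
        [
            ("island", seqs[island_tips[0].id]),
            ("mainland", seqs[mainland_tips[0].id]),
            ("outgroup", seqs[outgroup_tip.id]),
        ]
    )
    truth = dict(truth)
    truth["params"] = asdict(params)
    return island_aln, mainland_aln, triplet, truth


def simulate_dataset(out_dir, params_list: list[ScenarioParams]):
    """Write FASTA files, truth sidecars and a manifest for a full dataset.

    Fully deterministic given each scenario's seed.  Returns the manifest
    path.
    """
    if not params_list:
        raise ValueError("need at least one comparison")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, params in enumerate(params_list):
        cid = f"c{i + 1:03d}"
        isl_sp, main_sp, out_sp = f"{cid}_isl", f"{cid}_main", f"{cid}_out"
        island_aln, mainland_aln, triplet, truth = simulate_comparison(params)
        island_path = out_dir / f"{cid}_island.fasta"
        mainland_path = out_dir / f"{cid}_mainland.fasta"
        triplet_path = out_dir / f"{cid}_triplet.fasta"
        write_codon_alignment(island_aln, island_path)
        write_codon_alignment(mainland_aln, mainland_path)
        renamed = CodonAlignment(
            sequences=tuple(
                (new_id, seq)
                for new_id, (_, seq) in zip(
                    (isl_sp, main_sp, out_sp), triplet.sequences
                )
            ),
            genome=triplet.genome,
            genetic_code=triplet.genetic_code,
            masked=triplet.masked,
        )
        write_codon_alignment(renamed, triplet_path)
        with open(out_dir / f"{cid}_truth.json", "w") as handle:
            json.dump(truth, handle, indent=1, sort_keys=True)
        entries.append(
            ComparisonManifest(
                comparison_id=cid,
                island_species=(isl_sp,),
                mainland_species=(main_sp,),
                outgroup_species=out_sp,
                genome=params.genome,
                taxon_group=params.taxon_group,
                direction=params.direction,
                polymorphism_files={
                    isl_sp: island_path.name,
                    main_sp: mainland_path.name,
                },
                divergence_file=triplet_path.name,
                genetic_code=params.genetic_code,
            )
        )
    manifest_path = out_dir / "manifest.tsv"
    write_manifest(entries, manifest_path)
    return manifest_path
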