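"""End-to-end orchestration: per-comparison statistics and summary tables.

``run_dataset`` consumes a manifest and emits one summary table per headline
statistic (synonymous diversity, piN/(piN+piS), omega, DoS, dS, the Ne proxy)
with subgroup rows, plus per-comparison detail, scatter/histogram data for the
diversity-vs-divergence analyses, and the zero-diversity exclusion
re-analysis.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import DiversityStats, aggregate_species, diversity_stats
from .divergence import METHOD_TAG, LineageSubstitution, comparison_divergence
from .paired_stats import PairedSummary, correlate, summarize, wilcoxon_signed_rank
from .selection_stats import (
    DEFAULT_GAMMA_SHAPE,
    SelectionSummary,
    dn_fraction,
    dos,
    ne_proxy,
    pn_fraction,
)
from .seq_io import ComparisonManifest, read_codon_alignment, read_manifest

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ComparisonResult",
    "run_comparison",
    "run_dataset",
    "ne_comparison",
    "select_longest_alignment",
    "write_outputs",
]

#: Deterministic tie-break when alignments of different genomes have equal length.
GENOME_PRIORITY = ("mitochondrial", "nuclear", "chloroplast")


@dataclass(frozen=True)
class AnalysisConfig:
    beta: float = DEFAULT_GAMMA_SHAPE
    n_boot: int = 1000
    seed: int = 0
    divergence_mode: str = "average"  # or "consensus"
    exact_wilcoxon_threshold: int = 20


@dataclass
class ComparisonResult:
    """All statistics for one comparison, with per-stage error flags."""

    comparison_id: str
    genome: str
    taxon_group: str
    direction: str
    range_ratio: float | None
    alignment_length_nt: int
    island_diversity: DiversityStats | None = None
    mainland_diversity: DiversityStats | None = None
    branches: dict[str, LineageSubstitution] | None = None
    island_selection: SelectionSummary | None = None
    mainland_selection: SelectionSummary | None = None
    errors: list[str] = field(default_factory=list)

    def _div(self, side: str) -> DiversityStats | None:
        return self.island_diversity if side == "island" else self.mainland_diversity

    def pi_S(self, side: str) -> float | None:
        d = self._div(side)
        return None if d is None else d.pi_S

    def pi_N(self, side: str) -> float | None:
        d = self._div(side)
        return None if d is None else d.pi_N

    def dS(self, side: str) -> float | None:
        if self.branches is None or side not in self.branches:
            return None
        return self.branches[side].dS

    def omega(self, side: str) -> float | None:
        if self.branches is None or side not in self.branches:
            return None
        return self.branches[side].omega

    def selection(self, side: str) -> SelectionSummary | None:
        return self.island_selection if side == "island" else self.mainland_selection

    def pairwise_dS(self) -> float | None:
        """Island-branch + mainland-branch synonymous divergence."""
        di, dm = self.dS("island"), self.dS("mainland")
        if di is None or dm is None:
            return None
        return di + dm


def run_comparison(
    entry: ComparisonManifest,
    base_dir,
    config: AnalysisConfig | None = None,
) -> ComparisonResult:
    """Execute all stages for one manifest entry; errors are recorded, not raised."""
    config = config or AnalysisConfig()
    base = Path(base_dir)
    code = entry.default_genetic_code()
    result = ComparisonResult(
        comparison_id=entry.comparison_id,
        genome=entry.genome,
        taxon_group=entry.taxon_group,
        direction=entry.direction,
        range_ratio=entry.range_ratio,
        alignment_length_nt=0,
    )

    def per_clade_diversity(species: tuple[str, ...]) -> DiversityStats | None:
        stats = []
        for sid in species:
            path = entry.polymorphism_files.get(sid)
            if path is None:
                continue
            aln = read_codon_alignment(base / path, genetic_code=code, genome=entry.genome)
            result.alignment_length_nt = max(result.alignment_length_nt, aln.length_nt)
            stats.append(diversity_stats(aln))
        return aggregate_species(stats) if stats else None

    if entry.polymorphism_files:
        try:
            result.island_diversity = per_clade_diversity(entry.island_species)
            result.mainland_diversity = per_clade_diversity(entry.mainland_species)
        except Exception as exc:  # recorded, pipeline continues
            result.errors.append(f"diversity: {exc}")

    if entry.divergence_file is not None:
        try:
            aln = read_codon_alignment(
                base / entry.divergence_file, genetic_code=code, genome=entry.genome
            )
            result.alignment_length_nt = max(result.alignment_length_nt, aln.length_nt)
            result.branches = comparison_divergence(
                aln,
                list(entry.island_species),
                list(entry.mainland_species),
                entry.outgroup_species,
                mode=config.divergence_mode,
            )
        except Exception as exc:
            result.errors.append(f"divergence: {exc}")

    for side in ("island", "mainland"):
        div = result._div(side)
        branch = (result.branches or {}).get(side)
        pn = pn_fraction(div.pi_N, div.pi_S) if div is not None else None
        dn = dn_fraction(branch.dN, branch.dS) if branch is not None else None
        dos_value = (
            dos(branch.dN, branch.dS, div.pi_N, div.pi_S)
            if div is not None and branch is not None
            else None
        )
        proxy = (
            ne_proxy(div.pi_S, branch.dS)
            if div is not None and branch is not None and branch.dS > 0
            else None
        )
        summary = SelectionSummary(
            pn_fraction=pn, dn_fraction=dn, dos=dos_value, ne_proxy=proxy, beta=config.beta
        )
        if side == "island":
            result.island_selection = summary
        else:
            result.mainland_selection = summary
    return result


def select_longest_alignment(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """One observation per comparison_id: keep the longest alignment's genome.

    Ties break deterministically by :data:`GENOME_PRIORITY`.
    """
    by_id: dict[str, list[ComparisonResult]] = {}
    for r in results:
        by_id.setdefault(r.comparison_id, []).append(r)
    selected = []
    for cid, group in by_id.items():
        if len(group) > 1:
            group = sorted(
                group,
                key=lambda r: (-r.alignment_length_nt, GENOME_PRIORITY.index(r.genome)),
            )
            logger.info(
                "comparison %s: selected %s genome (longest alignment rule)",
                cid,
                group[0].genome,
            )
        selected.append(group[0])
    return selected


def _row_seed(base_seed: int, statistic: str, label: str) -> int:
    return (base_seed + zlib.crc32(f"{statistic}|{label}".encode())) % (2**31)


def _subgroups(results: list[ComparisonResult], with_direction: bool):
    yield "combined", results
    for genome in GENOME_PRIORITY:
        sub = [r for r in results if r.genome == genome]
        if sub:
            yield genome, sub
    taxa = sorted({r.taxon_group for r in results})
    for taxon in taxa:
        yield taxon, [r for r in results if r.taxon_group == taxon]
    if with_direction:
        for direction, tag in (("island_to_mainland", "I->M"), ("mainland_to_island", "M->I")):
            sub = [r for r in results if r.direction == direction]
            yield tag, sub
        m2i = [r for r in results if r.direction == "mainland_to_island"]
        for genome in GENOME_PRIORITY:
            sub = [r for r in m2i if r.genome == genome]
            if sub:
                yield f"M->I {genome}", sub
        for taxon in sorted({r.taxon_group for r in m2i}):
            yield f"M->I {taxon}", [r for r in m2i if r.taxon_group == taxon]


def _summary_table(
    results: list[ComparisonResult],
    statistic: str,
    island_getter,
    mainland_getter,
    tail: str,
    config: AnalysisConfig,
    with_direction: bool = False,
    spearman_vs_range: bool = False,
) -> pd.DataFrame:
    rows = []
    for label, sub in _subgroups(results, with_direction):
        summary = summarize(
            statistic,
            [island_getter(r) for r in sub],
            [mainland_getter(r) for r in sub],
            tail=tail,
            n_boot=config.n_boot,
            seed=_row_seed(config.seed, statistic, label),
        )
        row = {
            "dataset": label,
            "n": summary.n_comparisons,
            "mean_island": summary.mean_island,
            "mean_mainland": summary.mean_mainland,
            "mean_relative_island": summary.mean_relative_island,
            "ci_lower": summary.ci_lower,
            "ci_upper": summary.ci_upper,
            "wilcoxon_p": summary.wilcoxon_p,
            "tail": summary.tail,
        }
        if spearman_vs_range:
            row["spearman_rho_vs_range_ratio"] = _range_correlation(
                sub, island_getter, mainland_getter
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _range_correlation(sub, island_getter, mainland_getter) -> float:
    from .paired_stats import relative_value

    xs, ys = [], []
    for r in sub:
        if r.range_ratio is None:
            continue
        xi, xm = island_getter(r), mainland_getter(r)
        if xi is None or xm is None:
            continue
        rel = relative_value(xi, xm)
        if rel is None:
            continue
        xs.append(r.range_ratio)
        ys.append(rel)
    if len(xs) < 3:
        return float("nan")
    try:
        rho, _ = correlate(xs, ys, method="spearman")
    except ValueError:
        return float("nan")
    return rho


def _dos_table(results: list[ComparisonResult], config: AnalysisConfig) -> pd.DataFrame:
    """DoS summary: paired signed-rank on island-mainland DoS differences."""
    rows = []
    for label, sub in (
        ("combined", results),
        ("I->M", [r for r in results if r.direction == "island_to_mainland"]),
        ("M->I", [r for r in results if r.direction == "mainland_to_island"]),
    ):
        pairs = [
            (r.island_selection.dos, r.mainland_selection.dos)
            for r in sub
            if r.island_selection is not None
            and r.mainland_selection is not None
            and r.island_selection.dos is not None
            and r.mainland_selection.dos is not None
        ]
        if pairs:
            diffs = [i - m for i, m in pairs]
            try:
                p = wilcoxon_signed_rank(diffs, null_center=0.0, tail="two_sided")
            except ValueError:
                p = 1.0
            rows.append(
                {
                    "dataset": label,
                    "n": len(pairs),
                    "mean_island_dos": float(np.mean([i for i, _ in pairs])),
                    "mean_mainland_dos": float(np.mean([m for _, m in pairs])),
                    "wilcoxon_p": p,
                }
            )
        else:
            rows.append(
                {
                    "dataset": label,
                    "n": 0,
                    "mean_island_dos": np.nan,
                    "mean_mainland_dos": np.nan,
                    "wilcoxon_p": np.nan,
                }
            )
    return pd.DataFrame(rows)


def ratio_percent(relative: float) -> float:
    """Convert a relative island value r to an island/mainland percentage."""
    if not 0 <= relative < 1:
        return float("nan")
    return 100.0 * relative / (1.0 - relative)


def ne_comparison(
    results: list[ComparisonResult], config: AnalysisConfig | None = None
) -> PairedSummary:
    """Paired summary of the pi_S/d_S effective-population-size proxy.

    One-tailed (island < mainland), matching the headline test; the mean
    relative value and CI convert to island/mainland percentages via
    ``r / (1 - r)``.
    """
    config = config or AnalysisConfig()
    return summarize(
        "ne_proxy",
        [r.island_selection.ne_proxy if r.island_selection else None for r in results],
        [r.mainland_selection.ne_proxy if r.mainland_selection else None for r in results],
        tail="less",
        n_boot=config.n_boot,
        seed=_row_seed(config.seed, "ne_proxy", "combined"),
    )


def _per_comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        sel_i, sel_m = r.island_selection, r.mainland_selection
        rows.append(
            {
                "comparison_id": r.comparison_id,
                "genome": r.genome,
                "taxon_group": r.taxon_group,
                "direction": r.direction,
                "range_ratio": r.range_ratio,
                "alignment_length_nt": r.alignment_length_nt,
                "pi_S_island": r.pi_S("island"),
                "pi_S_mainland": r.pi_S("mainland"),
                "pi_N_island": r.pi_N("island"),
                "pi_N_mainland": r.pi_N("mainland"),
                "dS_island": r.dS("island"),
                "dS_mainland": r.dS("mainland"),
                "dS_outgroup": r.dS("outgroup"),
                "omega_island": r.omega("island"),
                "omega_mainland": r.omega("mainland"),
                "pn_fraction_island": sel_i.pn_fraction if sel_i else None,
                "pn_fraction_mainland": sel_m.pn_fraction if sel_m else None,
                "dos_island": sel_i.dos if sel_i else None,
                "dos_mainland": sel_m.dos if sel_m else None,
                "ne_proxy_island": sel_i.ne_proxy if sel_i else None,
                "ne_proxy_mainland": sel_m.ne_proxy if sel_m else None,
                "errors": ";".join(r.errors),
            }
        )
    return pd.DataFrame(rows)


def _figure_frames(results: list[ComparisonResult]):
    from .paired_stats import relative_value

    fig2_rows = []
    fig3_rows = []
    for r in results:
        pi_i, pi_m = r.pi_S("island"), r.pi_S("mainland")
        total_ds = r.pairwise_dS()
        if pi_i is not None and pi_m is not None and total_ds is not None:
            rel = relative_value(pi_i, pi_m)
            if rel is not None:
                fig2_rows.append(
                    {
                        "comparison_id": r.comparison_id,
                        "relative_island_pi_S": rel,
                        "pairwise_dS": total_ds,
                        "direction": r.direction,
                        "taxon_group": r.taxon_group,
                    }
                )
        if pi_i is not None and total_ds is not None and total_ds > 0:
            fig3_rows.append(
                {
                    "comparison_id": r.comparison_id,
                    "island_piS_over_dS": pi_i / total_ds,
                }
            )
    return pd.DataFrame(fig2_rows), pd.DataFrame(fig3_rows)


def run_dataset(manifest_path, config: AnalysisConfig | None = None) -> dict:
    """Run the full analysis for a manifest; returns a dict of DataFrames.

    Keys: ``per_comparison``, ``pi_S``, ``pn_fraction``, ``omega``, ``dos``,
    ``d_S``, ``ne``, ``pi_S_excluding_zero``, ``ne_excluding_zero``,
    ``fig2_data``, ``fig3_data``, ``provenance``.
    """
    config = config or AnalysisConfig()
    manifest_path = Path(manifest_path)
    entries = read_manifest(manifest_path)
    if not entries:
        raise ValueError("manifest contains no comparisons")
    base_dir = manifest_path.parent
    results = [run_comparison(e, base_dir, config) for e in entries]
    results = select_longest_alignment(results)

    tables: dict[str, object] = {}
    tables["per_comparison"] = _per_comparison_frame(results)
    tables["pi_S"] = _summary_table(
        results,
        "pi_S",
        lambda r: r.pi_S("island"),
        lambda r: r.pi_S("mainland"),
        tail="less",
        config=config,
        spearman_vs_range=True,
    )
    tables["pn_fraction"] = _summary_table(
        results,
        "pn_fraction",
        lambda r: r.island_selection.pn_fraction if r.island_selection else None,
        lambda r: r.mainland_selection.pn_fraction if r.mainland_selection else None,
        tail="greater",
        config=config,
    )
    tables["omega"] = _summary_table(
        results,
        "omega",
        lambda r: r.omega("island"),
        lambda r: r.omega("mainland"),
        tail="two_sided",
        config=config,
        with_direction=True,
    )
    tables["dos"] = _dos_table(results, config)
    tables["d_S"] = _summary_table(
        results,
        "d_S",
        lambda r: r.dS("island"),
        lambda r: r.dS("mainland"),
        tail="two_sided",
        config=config,
    )

    ne = ne_comparison(results, config)
    tables["ne"] = pd.DataFrame(
        [
            {
                "dataset": "combined",
                "n": ne.n_comparisons,
                "mean_relative_island": ne.mean_relative_island,
                "island_percent_of_mainland": ratio_percent(ne.mean_relative_island),
                "percent_ci_lower": ratio_percent(ne.ci_lower),
                "percent_ci_upper": ratio_percent(ne.ci_upper),
                "wilcoxon_p": ne.wilcoxon_p,
                "tail": ne.tail,
            }
        ]
    )

    # Zero-diversity exclusion re-analysis: drop comparisons whose island
    # synonymous diversity is exactly zero and recompute the headline tests.
    nonzero = [r for r in results if r.pi_S("island") not in (None, 0.0)]
    tables["pi_S_excluding_zero"] = _summary_table(
        nonzero,
        "pi_S_excluding_zero",
        lambda r: r.pi_S("island"),
        lambda r: r.pi_S("mainland"),
        tail="less",
        config=config,
    )
    ne_excl = ne_comparison(nonzero, config)
    tables["ne_excluding_zero"] = pd.DataFrame(
        [
            {
                "dataset": "combined",
                "n": ne_excl.n_comparisons,
                "mean_relative_island": ne_excl.mean_relative_island,
                "island_percent_of_mainland": ratio_percent(ne_excl.mean_relative_island),
                "wilcoxon_p": ne_excl.wilcoxon_p,
                "tail": ne_excl.tail,
            }
        ]
    )
    n_excluded = len(results) - len(nonzero)
    if n_excluded:
        logger.info("zero-diversity exclusion removed %d comparisons", n_excluded)

    fig2, fig3 = _figure_frames(results)
    tables["fig2_data"] = fig2
    tables["fig3_data"] = fig3
    if len(fig2) >= 3:
        try:
            r_val, p_val = correlate(
                fig2["pairwise_dS"], fig2["relative_island_pi_S"], method="pearson"
            )
        except ValueError:
            r_val, p_val = float("nan"), float("nan")
        tables["fig2_correlation"] = pd.DataFrame(
            [{"pearson_r": r_val, "p_value": p_val, "n": len(fig2)}]
        )

    tables["provenance"] = {
        "package_version": __version__,
        "divergence_method": METHOD_TAG,
        "config": {
            "beta": config.beta,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "divergence_mode": config.divergence_mode,
        },
        "n_manifest_entries": len(entries),
        "n_comparisons_after_genome_selection": len(results),
        "n_zero_diversity_excluded": n_excluded,
    }
    tables["results"] = results
    return tables


def write_outputs(tables: dict, out_dir) -> None:
    """Write every DataFrame as TSV plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    with open(out_dir / "provenance.json", "w") as handle:
        json.dump(tables.get("provenance", {}), handle, indent=1, sort_keys=True)
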