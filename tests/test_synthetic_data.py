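import json

import numpy as np
import pytest

from islepair.diversity import diversity_stats
from islepair.paired_stats import relative_value
from islepair.pipeline import run_dataset
from islepair.seq_io import read_codon_alignment, read_manifest
from islepair.synthetic_data import ScenarioParams, simulate_comparison, simulate_dataset


class TestScenarioParams:
    def test_defaults_valid(self):
        ScenarioParams()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_codons": 0},
            {"theta": -0.1},
            {"sample_sizes": (1, 5)},
            {"nonsyn_neutral_fraction": 1.5},
            {"bottleneck_founders": 0},
            {"migration_rate": -1.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioParams(**kwargs)


class TestSimulateComparison:
    def test_shapes_and_validity(self):
        p = ScenarioParams(n_codons=50, seed=7)
        island, mainland, triplet, truth = simulate_comparison(p)
        assert island.n_sequences == 5
        assert mainland.n_sequences == 5
        assert triplet.n_sequences == 3
        assert island.length_nt == 150
        assert triplet.ids == ("island", "mainland", "outgroup")
        assert truth["t_root"] >= truth["t_representative_pair"]
        # sequences are clean sense-codon DNA: diversity machinery accepts them
        diversity_stats(island)
        diversity_stats(mainland)

    def test_deterministic_given_seed(self):
        p = ScenarioParams(n_codons=40, seed=11)
        a = simulate_comparison(p)
        b = simulate_comparison(p)
        assert a[0].sequences == b[0].sequences
        assert a[2].sequences == b[2].sequences

    def test_extreme_bottleneck_erases_island_diversity(self):
        # single founder at a very recent split: island nearly monomorphic
        zeros = 0
        for s in range(20):
            p = ScenarioParams(
                n_codons=100,
                theta=0.02,
                split_time=0.001,
                bottleneck_founders=1,
                seed=s,
            )
            island, _, _, _ = simulate_comparison(p)
            if diversity_stats(island).pi_S == 0.0:
                zeros += 1
        assert zeros >= 18

    def test_no_selection_no_nonsyn_rejected(self):
        # nonsyn_neutral_fraction=0 removes every amino-acid change
        p = ScenarioParams(n_codons=100, theta=0.05, nonsyn_neutral_fraction=0.0, seed=3)
        island, mainland, triplet, _ = simulate_comparison(p)
        assert diversity_stats(island).pi_N == 0.0
        from islepair.divergence import assign_lineage_changes

        raw = assign_lineage_changes(triplet)
        assert all(v[1] == 0.0 for v in raw.values())

    def test_outgroup_much_more_diverged_than_island(self):
        p = ScenarioParams(n_codons=200, theta=0.01, outgroup_time=10.0, seed=5)
        island, _, triplet, _ = simulate_comparison(p)
        pi = diversity_stats(island).pi_total
        out = triplet.sequence("outgroup")
        isl = triplet.sequence("island")
        d = sum(1 for a, b in zip(out, isl) if a != b) / len(out)
        assert d > 5 * max(pi, 1e-4)


class TestNeutralCalibration:
    def test_mean_pi_s_matches_theta(self):
        """E[pi_S] = theta under neutrality (300 replicates, 3 SE)."""
        theta = 0.01
        vals = []
        for s in range(300):
            p = ScenarioParams(
                n_codons=150, theta=theta, seed=40_000 + s, split_time=0.0
            )
            island, _, _, _ = simulate_comparison(p)
            vals.append(diversity_stats(island).pi_S)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - theta) <= 3 * se

    def test_pi_s_unbiased_by_sample_size(self):
        """E[pi_S] is the same at n = 2, 5, 10 chromosomes."""
        means = {}
        ses = {}
        for n in (2, 5, 10):
            vals = []
            for s in range(250):
                p = ScenarioParams(
                    n_codons=120,
                    theta=0.01,
                    seed=50_000 + s,
                    split_time=0.0,
                    sample_sizes=(n, 2),
                )
                island, _, _, _ = simulate_comparison(p)
                vals.append(diversity_stats(island).pi_S)
            vals = np.asarray(vals)
            means[n] = vals.mean()
            ses[n] = vals.std(ddof=1) / np.sqrt(vals.size)
        for n in (5, 10):
            tol = 3 * np.hypot(ses[2], ses[n])
            assert abs(means[n] - means[2]) <= tol

    def test_exchangeable_demes_relative_pi_centered(self):
        rels = []
        for s in range(300):
            p = ScenarioParams(n_codons=100, theta=0.02, seed=60_000 + s)
            island, mainland, _, _ = simulate_comparison(p)
            r = relative_value(
                diversity_stats(island).pi_S, diversity_stats(mainland).pi_S
            )
            if r is not None:
                rels.append(r)
        rels = np.asarray(rels)
        se = rels.std(ddof=1) / np.sqrt(rels.size)
        assert abs(rels.mean() - 0.5) <= 3 * se


class TestBottleneckEffects:
    @staticmethod
    def _mean_relative_pi(founders, split_time, n_rep=150, seed0=70_000):
        rels = []
        for s in range(n_rep):
            p = ScenarioParams(
                n_codons=100,
                theta=0.02,
                split_time=split_time,
                bottleneck_founders=founders,
                seed=seed0 + s,
            )
            island, mainland, _, _ = simulate_comparison(p)
            r = relative_value(
                diversity_stats(island).pi_S, diversity_stats(mainland).pi_S
            )
            if r is not None:
                rels.append(r)
        return float(np.mean(rels))

    def test_relative_pi_monotone_in_founder_count(self):
        at = {
            f: self._mean_relative_pi(f, split_time=0.1)
            for f in (1, 2, 10, None)
        }
        assert at[1] < at[2] < at[None]
        assert at[10] <= at[None] + 0.02
        assert at[1] < 0.4

    def test_recovery_with_time_since_bottleneck(self):
        early = self._mean_relative_pi(2, split_time=0.05, seed0=80_000)
        late = self._mean_relative_pi(2, split_time=1.5, seed0=80_000)
        assert early < late

    def test_ds_dominates_pi_s_with_deep_outgroup(self):
        from islepair.divergence import triplet_substitutions

        ratios = []
        for s in range(40):
            p = ScenarioParams(
                n_codons=150, theta=0.01, outgroup_time=15.0, seed=90_000 + s
            )
            island, _, triplet, _ = simulate_comparison(p)
            subs = triplet_substitutions(triplet)
            total_ds = subs["island"].dS + subs["mainland"].dS + subs["outgroup"].dS
            if total_ds > 0:
                ratios.append(diversity_stats(island).pi_S / total_ds)
        assert np.mean(ratios) < 0.25  # d_S >> pi_S regime


class TestSimulateDataset:
    def test_files_and_manifest_round_trip(self, tmp_path):
        params = [ScenarioParams(n_codons=30, seed=s) for s in range(3)]
        manifest_path = simulate_dataset(tmp_path, params)
        entries = read_manifest(manifest_path)
        assert len(entries) == 3
        for entry in entries:
            for sid, fname in entry.polymorphism_files.items():
                aln = read_codon_alignment(tmp_path / fname)
                assert aln.n_sequences == 5
            tri = read_codon_alignment(tmp_path / entry.divergence_file)
            assert set(tri.ids) == set(
                entry.island_species + entry.mainland_species + (entry.outgroup_species,)
            )
            truth = json.loads((tmp_path / f"{entry.comparison_id}_truth.json").read_text())
            assert "t_root" in truth

    def test_byte_identical_given_seeds(self, tmp_path):
        params = [ScenarioParams(n_codons=20, seed=s) for s in range(2)]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(d1, params)
        simulate_dataset(d2, params)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_pipeline_consumes_output_unchanged(self, tmp_path):
        params = [ScenarioParams(n_codons=40, theta=0.02, seed=s) for s in range(3)]
        manifest_path = simulate_dataset(tmp_path, params)
        tables = run_dataset(manifest_path)
        assert len(tables["per_comparison"]) == 3

    def test_empty_params_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            simulate_dataset(tmp_path, [])
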