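"""Generator-level checks: determinism, planted structure, Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy import stats

from bcrep.airr_io import write_rearrangements
from bcrep.clones import assign_clones_identity
from bcrep.diversity import hill_number, p20
from bcrep.morbidity import morbidity_table
from bcrep.simulate import (
    CohortSpec,
    build_design,
    generate_cohort,
    generate_morbidity,
    generate_sample,
    make_germline_reference,
    population_usage,
)
from bcrep.util import substream


class TestGermlineReference:
    def test_entry_count(self):
        genes, lengths = make_germline_reference(20, 10, 4, seed=1)
        assert len(genes) == 34
        assert lengths["segment"].value_counts().to_dict() == {"V": 20, "D": 10, "J": 4}

    def test_segment_length_ranges_and_frame(self):
        genes, lengths = make_germline_reference(10, 5, 3, seed=3)
        by_seg = lengths.set_index("gene")
        for name, seq in genes.items():
            L = by_seg.loc[name, "length_nt"]
            assert len(seq) == L
            seg = by_seg.loc[name, "segment"]
            if seg == "V":
                assert 250 <= L <= 300 and L % 3 == 0
            elif seg == "J":
                assert 40 <= L <= 60 and L % 3 == 0
            else:
                assert 10 <= L <= 30

    def test_deterministic_given_seed(self, tmp_path):
        from bcrep.airr_io import write_germline_fasta

        a, _ = make_germline_reference(6, 3, 2, seed=11)
        b, _ = make_germline_reference(6, 3, 2, seed=11)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_germline_fasta(a, pa)
        write_germline_fasta(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            make_germline_reference(1, 0, 4, seed=1)


def _one_sample(spec, sample_id="AL_24m_m1_spleen", diet="AL", age=24, stream=0):
    genes, _ = make_germline_reference(spec.n_v, spec.n_d, spec.n_j, spec.seed)
    pop = population_usage(spec, spec.seed)
    meta = {"sample_id": sample_id, "tissue": "spleen", "diet": diet, "age_months": age}
    rng = substream(spec.seed, "sample", sample_id, stream)
    return generate_sample(spec, meta, genes, pop, rng)


class TestGenerateSample:
    def test_zero_sequences_gives_empty_output(self):
        spec = CohortSpec(seqs_per_sample=0, n_clones_base=50, n_v=4, n_d=2, n_j=2)
        df, truth = _one_sample(spec)
        assert len(df) == 0
        assert len(truth.clone_of_seq) == 0

    def test_uniform_concentration_p20_matches_multinomial_oracle(self):
        """Near-uniform clone sizes: sampled P20 agrees with a direct
        multinomial Monte-Carlo oracle, and the true (probability-level)
        P20 equals 20/C."""
        C, n, n_seeds = 500, 2000, 50
        spec = CohortSpec(
            seqs_per_sample=n, n_clones_base=C, alpha0=1e6,
            expansion_slope={"AL": 0.0, "DR": 0.0}, n_v=6, n_d=3, n_j=2,
            shm_rate={k: 0.0 for k in ("IgM", "IgD", "IgG", "IgE", "IgA")},
        )
        sampled = []
        for s in range(n_seeds):
            _, truth = _one_sample(spec, stream=s)
            counts = np.sort(truth.clone_counts)[::-1]
            sampled.append(counts[:20].sum() / n)
            assert truth.true_p20 == pytest.approx(20 / C, abs=1e-4)
        # independent oracle: multinomial sampling from the exactly uniform law
        rng = np.random.default_rng(12345)
        oracle = [
            np.sort(rng.multinomial(n, np.full(C, 1 / C)))[::-1][:20].sum() / n
            for _ in range(400)
        ]
        se = np.std(oracle) / np.sqrt(n_seeds)
        assert abs(np.mean(sampled) - np.mean(oracle)) < 3 * se

    def test_isotype_fractions_match_mix_within_binomial_error(self):
        spec = CohortSpec(
            seqs_per_sample=10_000, n_clones_base=200, n_v=6, n_d=3, n_j=2,
            shm_rate={k: 0.0 for k in ("IgM", "IgD", "IgG", "IgE", "IgA")},
        )
        df, _ = _one_sample(spec)
        mix = spec.isotype_mix["spleen"]
        frac = df["isotype"].value_counts(normalize=True)
        for iso, p in mix.items():
            se = np.sqrt(p * (1 - p) / len(df))
            assert abs(frac.get(iso, 0.0) - p) < 3 * se, iso

    def test_ground_truth_partition_covers_each_sequence_once(self, small_sample):
        df, truth = small_sample
        assert len(truth.clone_of_seq) == len(df)
        assert truth.clone_counts.sum() == len(df)
        np.testing.assert_array_equal(
            np.bincount(truth.clone_of_seq, minlength=len(truth.clone_probs)),
            truth.clone_counts,
        )

    def test_identity_assignment_recovers_planted_partition(self, small_sample):
        """Junction mutations are never planted, so the identity rule must
        reproduce the planted clone partition exactly (Rand index 1)."""
        from sklearn.metrics import rand_score

        df, truth = small_sample
        part = assign_clones_identity(df)
        pred = part.assignments.loc[df["sequence_id"]].to_numpy()
        assert rand_score(truth.clone_of_seq, pd_codes(pred)) == 1.0

    def test_expansion_slope_shifts_p20_up_and_shannon_down(self):
        """Steeper expansion slope => larger expected P20, smaller expected
        Shannon diversity, checked over seeds."""
        def mean_metrics(slope, n_seeds=8):
            spec = CohortSpec(
                seqs_per_sample=800, n_clones_base=300, n_v=6, n_d=3, n_j=2,
                expansion_slope={"AL": slope, "DR": slope},
                shm_rate={k: 0.0 for k in ("IgM", "IgD", "IgG", "IgE", "IgA")},
            )
            p20s, shannons = [], []
            for s in range(n_seeds):
                df, truth = _one_sample(spec, stream=(slope, s))
                part = assign_clones_identity(df)
                p20s.append(p20(part).p20)
                shannons.append(hill_number(part.abundances(), 1.0))
            return np.mean(p20s), np.mean(shannons)

        p_low, h_low = mean_metrics(0.02)
        p_high, h_high = mean_metrics(0.12)
        assert p_high > p_low
        assert h_high < h_low


def pd_codes(arr):
    import pandas as pd

    return pd.factorize(arr)[0]


class TestCohortDeterminism:
    def test_same_spec_and_seed_byte_identical(self, tmp_path, small_spec):
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_rearrangements(generate_cohort(small_spec).samples, pa)
        write_rearrangements(generate_cohort(small_spec).samples, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_design_respects_switch_age(self):
        spec = CohortSpec(ages=(5, 16, 20, 24))
        design = build_design(spec)
        aldr = design[design["diet"] == "AL_DR16M"]
        assert aldr["age_months"].min() == 16
        assert set(design.loc[design["diet"] == "AL", "age_months"]) == {5, 16, 20, 24}


class TestGenerateMorbidity:
    def _drivers(self, n, rng):
        return {f"m{i:03d}": float(v) for i, v in enumerate(rng.normal(size=n))}

    def test_zero_coupling_gives_null_correlation(self):
        """With coupling 0 the index is pure noise: Spearman rho against the
        planted driver stays inside the permutation null band (200 mice)."""
        rng = np.random.default_rng(5)
        drivers = self._drivers(200, rng)
        records = generate_morbidity(drivers, coupling=0.0, noise_sd=1.0, rng=rng)
        table = morbidity_table(records).set_index("mouse_id")
        x = np.array([drivers[m] for m in table.index])
        rho, _ = stats.spearmanr(x, table["macromorbidity"])
        # permutation oracle for the null band of |rho| at n = 200
        perm_rng = np.random.default_rng(99)
        y = table["macromorbidity"].to_numpy(float)
        null = [
            abs(stats.spearmanr(perm_rng.permutation(x), y)[0]) for _ in range(500)
        ]
        assert abs(rho) <= np.quantile(null, 0.995)

    def test_strong_coupling_without_noise_is_monotone(self):
        rng = np.random.default_rng(6)
        drivers = self._drivers(60, rng)
        records = generate_morbidity(drivers, coupling=5.0, noise_sd=0.0, rng=rng)
        table = morbidity_table(records).set_index("mouse_id")
        order = sorted(drivers, key=drivers.get)
        idx = table.loc[order, "macromorbidity"].to_numpy()
        assert (np.diff(idx) >= 0).all()
        rho, _ = stats.spearmanr([drivers[m] for m in order], idx)
        assert rho > 0.9

    def test_single_mouse_is_representable(self):
        rng = np.random.default_rng(7)
        (rec,) = generate_morbidity({"m1": 0.3}, coupling=1.0, noise_sd=0.0, rng=rng)
        assert rec.mouse_id == "m1"
        assert morbidity_table([rec])["macromorbidity"].iloc[0] >= 0
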