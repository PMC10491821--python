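"""Paired FSH-response analysis: mixed ANOVA and permutation tests."""

import itertools

import numpy as np
import pytest

from hatchsex import (
    GeneratorConfig,
    PairedSample,
    generate_paired_fsh,
    pair_records,
    permutation_change_test,
    ranova_paired,
)
from hatchsex.errors import DesignError, DomainError, InsufficientDataError, PairingError


def _pairs_from_logs(f_pairs, m_pairs):
    out = []
    for i, (a, b) in enumerate(f_pairs):
        out.append(PairedSample(f"F{i}", "F", np.exp(a), np.exp(b)))
    for i, (a, b) in enumerate(m_pairs):
        out.append(PairedSample(f"M{i}", "M", np.exp(a), np.exp(b)))
    return out


class TestRanova:
    def test_identical_shift_gives_zero_interaction(self):
        cfg = GeneratorConfig(n_female=8, n_male=8, fsh_shift=(0.7, 0.7), fsh_noise_sd=0.0, seed=2)
        pairs = pair_records(generate_paired_fsh(cfg))
        res = ranova_paired(pairs)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-18)

    def test_zero_residual_divergent_interaction(self):
        """Within-subject change differs by sex with zero residual variance:
        the interaction F diverges."""
        pairs = _pairs_from_logs([(0, 1), (0, 1)], [(1, 3), (1, 3)])
        res = ranova_paired(pairs)
        assert res.f_interaction == np.inf
        assert res.p_interaction == 0.0

    def test_degrees_of_freedom(self):
        cfg = GeneratorConfig(n_female=9, n_male=14, seed=3)
        res = ranova_paired(pair_records(generate_paired_fsh(cfg)))
        assert res.df == (1, 21)

    def test_matches_general_mixed_anova(self):
        """Cross-check against an independent general-purpose mixed ANOVA
        implementation on an unbalanced synthetic design."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        cfg = GeneratorConfig(n_female=9, n_male=14, fsh_shift=(0.5, 1.1), fsh_noise_sd=0.4, seed=7)
        pairs = pair_records(generate_paired_fsh(cfg))
        mine = ranova_paired(pairs, log_transform=True)
        rows = []
        for p in pairs:
            rows.append({"id": p.individual_id, "sex": p.sex, "status": "naive", "y": np.log(p.t_naive)})
            rows.append({"id": p.individual_id, "sex": p.sex, "status": "challenged", "y": np.log(p.t_challenged)})
        aov = pg.mixed_anova(
            data=pd.DataFrame(rows), dv="y", within="status", between="sex", subject="id"
        ).set_index("Source")
        assert mine.f_interaction == pytest.approx(aov.loc["Interaction", "F"], rel=1e-9)
        assert mine.f_sex == pytest.approx(aov.loc["sex", "F"], rel=1e-9)

    def test_challenge_main_effect_matches_reference_when_balanced(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        cfg = GeneratorConfig(n_female=10, n_male=10, fsh_shift=(0.6, 1.2), fsh_noise_sd=0.3, seed=8)
        pairs = pair_records(generate_paired_fsh(cfg))
        mine = ranova_paired(pairs)
        rows = []
        for p in pairs:
            rows.append({"id": p.individual_id, "sex": p.sex, "status": "naive", "y": np.log(p.t_naive)})
            rows.append({"id": p.individual_id, "sex": p.sex, "status": "challenged", "y": np.log(p.t_challenged)})
        aov = pg.mixed_anova(
            data=pd.DataFrame(rows), dv="y", within="status", between="sex", subject="id"
        ).set_index("Source")
        assert mine.f_challenge == pytest.approx(aov.loc["status", "F"], rel=1e-9)

    def test_scale_equivariance_on_log_scale(self):
        cfg = GeneratorConfig(n_female=6, n_male=9, fsh_shift=(0.4, 1.0), fsh_noise_sd=0.3, seed=5)
        pairs = pair_records(generate_paired_fsh(cfg))
        scaled = [
            PairedSample(p.individual_id, p.sex, 7.3 * p.t_naive, 7.3 * p.t_challenged)
            for p in pairs
        ]
        a, b = ranova_paired(pairs), ranova_paired(scaled)
        assert a.f_interaction == pytest.approx(b.f_interaction, rel=1e-9)
        assert a.f_challenge == pytest.approx(b.f_challenge, rel=1e-9)

    def test_positive_challenge_effect_when_both_sexes_increase(self):
        cfg = GeneratorConfig(n_female=10, n_male=15, fsh_shift=(0.9, 1.0), fsh_noise_sd=0.2, seed=6)
        pairs = pair_records(generate_paired_fsh(cfg))
        res = ranova_paired(pairs)
        assert res.f_challenge > 10
        assert res.p_challenge < 0.001

    def test_single_sex_design_rejected(self):
        pairs = _pairs_from_logs([(0, 1), (0, 2), (1, 2)], [])
        with pytest.raises(DesignError):
            ranova_paired(pairs)

    def test_power_for_large_sex_difference(self):
        """delta_m - delta_f = 2 with small noise: interaction detected at
        p < 0.001 in virtually every replicate."""
        hits = 0
        for seed in range(60):
            cfg = GeneratorConfig(
                n_female=50, n_male=50, fsh_shift=(0.0, 2.0), fsh_noise_sd=0.1, seed=seed
            )
            res = ranova_paired(pair_records(generate_paired_fsh(cfg)))
            hits += res.p_interaction < 0.001
        assert hits >= 59


class TestPairing:
    def test_incomplete_individuals_dropped_with_warning(self):
        cfg = GeneratorConfig(n_female=3, n_male=3, seed=1)
        records = generate_paired_fsh(cfg)
        records = records[:-1]  # drop one challenged sample
        with pytest.warns(UserWarning, match="dropped 1"):
            pairs = pair_records(records)
        assert len(pairs) == 5

    def test_duplicate_sample_rejected(self):
        cfg = GeneratorConfig(n_female=3, n_male=3, seed=1)
        records = generate_paired_fsh(cfg)
        with pytest.raises(PairingError):
            pair_records(records + [records[0]])

    def test_every_pair_links_naive_and_challenged(self):
        cfg = GeneratorConfig(n_female=4, n_male=5, seed=9)
        records = generate_paired_fsh(cfg)
        pairs = pair_records(records)
        assert len(pairs) == 9
        by_id = {p.individual_id for p in pairs}
        assert len(by_id) == 9


class TestPermutation:
    def test_identical_changes_give_null_result(self):
        pairs = _pairs_from_logs([(0, 1), (1, 2), (2, 3)], [(0, 1), (1, 2), (2, 3)])
        # equal multiplicative change but different absolute change; use logs
        pairs = [
            PairedSample(p.individual_id, p.sex, 10.0, 15.0) for p in pairs
        ]
        obs, p = permutation_change_test(pairs, "absolute", n_perm=999, seed=0)
        assert obs == pytest.approx(0.0)
        assert p == 1.0

    def test_matches_exhaustive_enumeration_at_n6(self):
        """Monte Carlo permutation p agrees with the brute-force enumeration
        over all 20 label splits of 3 F + 3 M individuals."""
        rng = np.random.default_rng(21)
        pairs = []
        for i, sex in enumerate("FFFMMM"):
            pre = float(rng.uniform(5, 30))
            post = pre * float(rng.uniform(1.2, 4.0 if sex == "M" else 2.0))
            pairs.append(PairedSample(f"i{i}", sex, pre, post))
        change = np.array([p.t_challenged - p.t_naive for p in pairs])
        observed = change[3:].mean() - change[:3].mean()
        count = 0
        splits = list(itertools.combinations(range(6), 3))
        for m_idx in splits:
            f_idx = [i for i in range(6) if i not in m_idx]
            stat = change[list(m_idx)].mean() - change[f_idx].mean()
            count += abs(stat) >= abs(observed) - 1e-12
        exact_p = count / len(splits)
        obs, p = permutation_change_test(pairs, "absolute", n_perm=19_999, seed=2)
        assert obs == pytest.approx(observed)
        assert p == pytest.approx(exact_p, abs=0.02)

    def test_p_on_grid_and_never_zero(self):
        cfg = GeneratorConfig(n_female=5, n_male=5, fsh_shift=(0.0, 3.0), fsh_noise_sd=0.05, seed=3)
        pairs = pair_records(generate_paired_fsh(cfg))
        n_perm = 999
        _, p = permutation_change_test(pairs, "percent", n_perm=n_perm, seed=4)
        assert p > 0.0
        assert round(p * (n_perm + 1)) == pytest.approx(p * (n_perm + 1), abs=1e-9)

    def test_seeded_reproducibility(self):
        cfg = GeneratorConfig(n_female=5, n_male=6, seed=10)
        pairs = pair_records(generate_paired_fsh(cfg))
        a = permutation_change_test(pairs, "absolute", 999, seed=11)
        b = permutation_change_test(pairs, "absolute", 999, seed=11)
        assert a == b

    def test_input_validation(self):
        cfg = GeneratorConfig(n_female=5, n_male=5, seed=0)
        pairs = pair_records(generate_paired_fsh(cfg))
        with pytest.raises(DomainError):
            permutation_change_test(pairs, "log", 999)
        with pytest.raises(InsufficientDataError):
            permutation_change_test(pairs, "absolute", 99)
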