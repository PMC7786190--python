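import numpy as np
import pytest

import sugarshock as ss
from sugarshock.ensemble import BasalSpec, CountDistribution, GeneConfiguration
from sugarshock.errors import ConfigurationError, DataError
from sugarshock.network import SpeciesState


def test_gene_dosage_frequencies_match_configured_fractions(rng):
    """P(4 sgrS copies) = 25% and P(2 ptsG copies) = 46%, independent."""
    p = ss.WT
    draws = np.array(
        [
            (c.n_sgrS_genes, c.n_ptsG_genes)
            for c in (ss.sample_gene_configuration(p, rng) for _ in range(100_000))
        ]
    )
    f_s = (draws[:, 0] == 4).mean()
    f_p = (draws[:, 1] == 2).mean()
    assert abs(f_s - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 100_000)
    assert abs(f_p - 0.46) < 3 * np.sqrt(0.46 * 0.54 / 100_000)
    # independence: joint frequency factorizes within Monte-Carlo error
    joint = ((draws[:, 0] == 4) & (draws[:, 1] == 2)).mean()
    assert abs(joint - f_s * f_p) < 0.01


@pytest.mark.parametrize(
    "fractions, expected",
    [({"f_high_sgrS": 1.0}, 4), ({"f_high_sgrS": 0.0}, 2)],
)
def test_degenerate_sgrs_fractions(rng, fractions, expected):
    p = ss.WT.replace(**fractions)
    assert all(
        ss.sample_gene_configuration(p, rng).n_sgrS_genes == expected
        for _ in range(50)
    )


def test_zero_high_fraction_always_single_ptsg_copy(rng):
    p = ss.WT.replace(f_high_ptsG=0.0)
    assert all(
        ss.sample_gene_configuration(p, rng).n_ptsG_genes == 1 for _ in range(50)
    )


def test_initial_state_layout(rng):
    config = GeneConfiguration(4, 2)
    state = ss.sample_initial_state(ss.WT, config, BasalSpec(), rng)
    assert state.Ds_off == 4 and state.Ds_on == 0  # all sgrS genes start OFF
    assert state.Dp == 2
    assert state.H == 250 and state.HS == 0 and state.HSP == 0
    assert 1 <= state.S <= 3
    assert 30 <= state.P <= 40


def test_basal_ptsg_mean_is_35(rng):
    """Mean of the default basal ptsG distribution, uniform {30..40}."""
    spec = BasalSpec()
    draws = spec.ptsg.sample(rng, size=100_000)
    assert abs(draws.mean() - 35.0) < 0.1
    assert spec.ptsg.mean == pytest.approx(35.0)


def test_degenerate_basal_spec_gives_rna_free_state(rng):
    spec = BasalSpec(
        sgrs=CountDistribution((0,), (1.0,)), ptsg=CountDistribution((0,), (1.0,))
    )
    state = ss.sample_initial_state(ss.WT, GeneConfiguration(2, 1), spec, rng)
    assert state.S == 0 and state.P == 0


def test_negative_basal_support_rejected():
    with pytest.raises(DataError):
        CountDistribution((-1, 0), (0.5, 0.5))


def test_invalid_gene_configuration_rejected():
    with pytest.raises(ConfigurationError):
        GeneConfiguration(3, 1)
    with pytest.raises(ConfigurationError):
        GeneConfiguration(2, 4)


def test_observables_count_complexed_rna():
    state = SpeciesState(S=2, HS=5, HSP=3, P=10, H=232)
    assert ss.observables(state) == (10, 13)
    assert ss.observables(SpeciesState(H=250)) == (0, 0)


def test_single_replicate_ensemble_has_all_snapshots(wt):
    ens = ss.run_ensemble(wt, "FULL", n_replicates=1, base_seed=3)
    assert ens.n_replicates == 1
    assert ens.counts.shape == (1, 8, 8)
    np.testing.assert_allclose(ens.schedule_min, [0, 2, 4, 6, 8, 10, 15, 20])


def test_ensemble_deterministic_given_base_seed(wt):
    a = ss.run_ensemble(wt, "FULL", n_replicates=20, base_seed=7)
    b = ss.run_ensemble(wt, "FULL", n_replicates=20, base_seed=7)
    assert np.array_equal(a.counts, b.counts)
    assert np.array_equal(a.gene_configs, b.gene_configs)


def test_hfq_conserved_at_every_snapshot(wt_ensemble):
    total = (
        wt_ensemble.species_counts("H")
        + wt_ensemble.species_counts("HS")
        + wt_ensemble.species_counts("HSP")
    )
    assert np.all(total == 250)


def test_gene_totals_constant_within_replicates(wt_ensemble):
    ds = wt_ensemble.species_counts("Ds_off") + wt_ensemble.species_counts("Ds_on")
    assert np.all(ds == wt_ensemble.gene_configs[:, [0]])
    assert np.all(
        wt_ensemble.species_counts("Dp") == wt_ensemble.gene_configs[:, [1]]
    )


def test_no_silencing_reduces_ptsg_to_dosage_poisson_mixture(wt):
    """With annealing off, late-time total ptsG has mean
    k_t_p * E[gene copies] / beta_p (Poisson mixture over dosage)."""
    p = ss.WT.replace(k_on=0.0)
    ens = ss.run_ensemble(p, "FULL", n_replicates=400, base_seed=11)
    _, total_p = ens.totals()
    late = total_p[:, -1].astype(float)
    expected = 0.12 * (0.46 * 2 + 0.54 * 1) / 0.0037
    se = late.std(ddof=1) / np.sqrt(late.size)
    assert abs(late.mean() - expected) < 3 * se + 0.5  # small relaxation remnant


def test_mean_ptsg_trace_monotone_decreasing_after_two_minutes(wt_ensemble):
    _, total_p = wt_ensemble.totals()
    means = total_p.mean(axis=0)
    assert np.all(np.diff(means[1:]) < 0.5)  # Monte-Carlo tolerance


def test_ensemble_means_stable_across_base_seeds(wt):
    a = ss.run_ensemble(wt, "FULL", n_replicates=500, base_seed=100_000)
    b = ss.run_ensemble(wt, "FULL", n_replicates=500, base_seed=900_000)
    for totals_a, totals_b in zip(a.totals(), b.totals()):
        se = np.sqrt(
            totals_a.var(axis=0, ddof=1) / 500 + totals_b.var(axis=0, ddof=1) / 500
        )
        diff = np.abs(totals_a.mean(axis=0) - totals_b.mean(axis=0))
        assert np.all(diff < 3 * se + 1e-9)


def test_ensemble_means_match_mean_field_ode(wt_ensemble):
    """Dosage-averaged mean-field ODE of the same network reproduces the
    SSA ensemble means of both labeled totals within a few percent (the
    system is only weakly nonlinear at these copy numbers)."""
    from scipy.integrate import solve_ivp

    p = wt_ensemble.params
    t_eval = wt_ensemble.schedule_min * 60.0

    def mixture_component(n_gs, n_gp):
        def rhs(_, y):
            on, s, hs, pm, hsp = y
            h = p.hfq_pool - hs - hsp
            bind = (p.k_bind / p.hfq_pool) * s * h
            anneal = p.k_on * hs * pm
            return [
                p.k_on_Ds * (n_gs - on) - p.k_off_Ds * on,
                p.k_t_s * on - p.k_ds * s - bind,
                bind - p.k_unbind * hs - anneal + p.k_off * hsp,
                p.k_t_p * n_gp - p.beta_p * pm - anneal + p.k_off * hsp,
                anneal - (p.k_off + p.k_cat) * hsp,
            ]

        sol = solve_ivp(rhs, [0, t_eval[-1]], [0, 2.0, 0, 35.0, 0],
                        t_eval=t_eval, rtol=1e-8, atol=1e-8)
        on, s, hs, pm, hsp = sol.y
        return s + hs + hsp, pm + hsp

    ode_sgrs = np.zeros_like(t_eval)
    ode_ptsg = np.zeros_like(t_eval)
    for n_gs, w_s in ((4, p.f_high_sgrS), (2, 1 - p.f_high_sgrS)):
        for n_gp, w_p in ((2, p.f_high_ptsG), (1, 1 - p.f_high_ptsG)):
            comp_s, comp_p = mixture_component(n_gs, n_gp)
            ode_sgrs += w_s * w_p * comp_s
            ode_ptsg += w_s * w_p * comp_p
    sim_sgrs, sim_ptsg = (t.mean(axis=0) for t in wt_ensemble.totals())
    # compare after t=0 (identical by construction); residual tolerance
    # covers molecular-level covariance terms absent from the mean field
    np.testing.assert_allclose(sim_sgrs[1:], ode_sgrs[1:], rtol=0.06)
    np.testing.assert_allclose(sim_ptsg[1:], ode_ptsg[1:], rtol=0.10)


def test_tidy_export_schema_and_round_trip(wt):
    ens = ss.run_ensemble(wt, "FULL", n_replicates=5, base_seed=2)
    tidy = ens.to_tidy()
    assert list(tidy.columns) == [
        "replicate", "time_min", "n_sgrS_genes", "n_ptsG_genes",
        "total_sgrs", "total_ptsg",
    ]
    assert len(tidy) == 5 * 8
    ds = ens.to_dataset()
    assert ds.provenance == "simulated"
    s0 = ds.counts(0.0, "sgrs")
    assert np.all((s0 >= 1) & (s0 <= 3))


def test_baseline_variant_runs_single_copies(wt):
    ens = ss.run_ensemble(wt, "NO_HFQ_NO_GENEDUP", n_replicates=30, base_seed=5)
    assert np.all(ens.gene_configs == 1)
    assert np.all(ens.species_counts("H") == 0)
    assert np.all(ens.species_counts("HS") == 0)
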