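import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from flornet.data_model import ConditionKey, Trajectory
from flornet.ode_models import (
    MODELED_GENES,
    ConfigurationError,
    DataRegulators,
    ParameterSet,
    apical_totals,
    apply_genotype,
    closed_form_solution,
    competitive_complexes,
    genotype_spec,
    half_life_to_rate,
    model_spec,
    noncompetitive_complexes,
    rhs_gene,
    simulate_gene,
    synthesis_rate,
)

MC = model_spec("MC")
MM = model_spec("MM")
WT_LD = ConditionKey("WT", "LD")

pos = st.floats(0.01, 50, allow_nan=False)


# ---------------------------------------------------------------------------
# rates and binding algebra
# ---------------------------------------------------------------------------

def test_half_life_to_rate():
    assert half_life_to_rate(3.49) == pytest.approx(0.199, abs=5e-4)
    assert half_life_to_rate(np.log(2)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        half_life_to_rate(0.0)


def test_competitive_complexes_examples():
    assert competitive_complexes(0, 0, 0, 5, 1, 1, 1) == (0, 0, 0)
    c = competitive_complexes(1, 1, 1, 4, 1, 1, 1)
    assert np.allclose(c, (1.0, 1.0, 1.0))  # 1*1*4 / (1+3)
    # saturation: one huge-affinity ligand monopolizes the whole VEG2 pool
    a1, b2, _ = competitive_complexes(1.0, 0.0, 0.0, 2.0, 1e12, 1.0, 1.0)
    assert a1 == pytest.approx(2.0, rel=1e-9) and b2 == 0.0
    with pytest.raises(ValueError):
        competitive_complexes(-1, 0, 0, 1, 1, 1, 1)


@given(uFTa1=pos, uFTb2=pos, uFTc=pos, uVEG2=pos,
       K13=pos, K14=pos, K15=pos)
def test_competitive_complexes_conserve_veg2(uFTa1, uFTb2, uFTc, uVEG2, K13, K14, K15):
    cs = competitive_complexes(uFTa1, uFTb2, uFTc, uVEG2, K13, K14, K15)
    assert all(0 <= c <= uVEG2 for c in cs)
    assert sum(cs) < uVEG2


def test_noncompetitive_complexes_are_products():
    assert noncompetitive_complexes(2, 0, 0, 3)[0] == 6.0
    assert noncompetitive_complexes(1, 1, 1, 0) == (0, 0, 0)
    with pytest.raises(ValueError):
        noncompetitive_complexes(1, 1, -1, 1)


def test_dilute_limit_agreement():
    """Competitive binding reduces to K_j-scaled products when K*u << 1."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        u = rng.uniform(0, 1e-4, size=4)
        K = rng.uniform(0.1, 2.0, size=3)
        comp = competitive_complexes(*u, *K)
        prod = noncompetitive_complexes(*u)
        for c, p, k in zip(comp, prod, K):
            assert c == pytest.approx(k * p, rel=1e-3)


# ---------------------------------------------------------------------------
# transport delay
# ---------------------------------------------------------------------------

def test_apical_totals():
    leaf_a1 = Trajectory("FTa1", "leaf", [7.0, 14.0], [2.0, 4.0])
    leaf_b2 = Trajectory("FTb2", "leaf", [7.0, 14.0], [0.0, 0.0])
    a1, b2 = apical_totals(14.0, 1.0, leaf_a1, leaf_b2, tau=3.5)
    assert a1 == pytest.approx(1.0 + 3.0)  # leaf value interpolated at t-tau=10.5
    assert b2 == 0.0
    a1_0, _ = apical_totals(14.0, 1.0, leaf_a1, leaf_b2, tau=0.0)
    assert a1_0 == pytest.approx(1.0 + 4.0)
    # delay beyond the data window clamps to the first leaf value
    a1_c, _ = apical_totals(8.0, 0.5, leaf_a1, leaf_b2, tau=10.0)
    assert a1_c == pytest.approx(0.5 + 2.0)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

ZERO_REGS = {k: 0.0 for k in ("VEG2FTa1", "VEG2FTb2", "VEG2FTc", "DET", "PIM", "LF", "VEG1")}


def test_rhs_at_zero_regulators():
    p = ParameterSet()
    # LF's repression term equals 1 at zero input; all activations vanish
    assert rhs_gene(MC, "LF", 0.0, 0.0, p, ZERO_REGS) == pytest.approx(p.v4)
    for gene in ("DET", "PIM", "VEG1", "FTc", "FTa1_apex"):
        assert rhs_gene(MC, gene, 0.0, 0.0, p, ZERO_REGS) == 0.0


def test_rhs_half_saturation():
    p = ParameterSet(v2=2.0, K3=1.5, K4=0.7, n=1.0)
    regs = dict(ZERO_REGS, VEG2FTa1=p.K3, DET=p.K4)
    assert rhs_gene(MC, "PIM", 0.0, 0.0, p, regs) == pytest.approx(p.v2 * 0.5 * 0.5)


def test_rhs_missing_regulator_names_gene():
    with pytest.raises(ConfigurationError, match="PIM.*VEG2FTa1"):
        synthesis_rate(MC, "PIM", ParameterSet(), {"DET": 0.0})


def _literal_rhs(gene, u, p, r):
    """Independent transcription of the six equations, written longhand."""
    if gene == "DET":
        return (p.v1 * r["VEG2FTb2"] / (p.K1 + r["VEG2FTb2"])
                * p.K2 / (p.K2 + r["VEG1"]) - p.lam * u)
    if gene == "PIM":
        return (p.v2 * r["VEG2FTa1"] ** p.n / (p.K3 ** p.n + r["VEG2FTa1"] ** p.n)
                * p.K4 / (p.K4 + r["DET"]) - p.lam * u)
    if gene == "VEG1":
        return (p.v3 * r["VEG2FTa1"] / (p.K5 + r["VEG2FTa1"])
                * p.K6 / (p.K6 + r["DET"]) * p.K7 / (p.K7 + r["PIM"])
                * p.K8 / (p.K8 + r["LF"]) - p.lam * u)
    if gene == "LF":
        return p.v4 * p.K9 / (p.K9 + r["VEG2FTb2"]) - p.lam * u
    if gene == "FTc":
        return (p.v5 * (r["VEG2FTa1"] / (p.K10 + r["VEG2FTa1"])
                        + r["VEG2FTb2"] / (p.K11 + r["VEG2FTb2"])) - p.lam * u)
    if gene == "FTa1_apex":
        return p.v6 * r["VEG2FTb2"] / (p.K12 + r["VEG2FTb2"]) - p.lam * u
    raise AssertionError(gene)


def test_rhs_matches_independent_transcription():
    rng = np.random.default_rng(7)
    for _ in range(100):
        kw = {f"v{i}": rng.uniform(0.1, 5) for i in range(1, 7)}
        kw.update({f"K{i}": rng.uniform(0.1, 5) for i in range(1, 13)})
        p = ParameterSet(n=rng.uniform(1, 3), **kw)
        regs = {k: rng.uniform(0, 10) for k in ZERO_REGS}
        u = rng.uniform(0, 5)
        gene = MODELED_GENES[rng.integers(0, 6)]
        spec = model_spec("MC_PIM") if gene == "PIM" else MC
        got = rhs_gene(spec, gene, 0.0, u, p, regs)
        want = _literal_rhs(gene, u, p, regs)
        assert got == pytest.approx(want, rel=1e-12)


def test_variant_reductions():
    rng = np.random.default_rng(3)
    regs = {k: rng.uniform(0, 5) for k in ZERO_REGS}
    p = ParameterSet(n=1.0)
    # MC_PIM with n=1 is exactly MC
    assert synthesis_rate(model_spec("MC_PIM"), "PIM", p, regs) == \
        synthesis_rate(MC, "PIM", p, regs)
    # MM_LF with K16 -> infinity loses the extra repression, back to MM
    p_inf = ParameterSet(K16=1e12)
    assert synthesis_rate(model_spec("MM_LF"), "PIM", p_inf, regs) == \
        pytest.approx(synthesis_rate(MM, "PIM", p_inf, regs), rel=1e-10)
    # FTa1 self-activation contributes nothing when its complex is absent
    regs0 = dict(regs, VEG2FTa1=0.0)
    assert synthesis_rate(model_spec("MC_Cdata_FTa1"), "FTa1_apex", ParameterSet(), regs0) == \
        synthesis_rate(MC, "FTa1_apex", ParameterSet(), regs0)


def test_synthesis_terms_bounded():
    """Activations sit in [0, v) and repressions in (0, v]; u stays bounded."""
    rng = np.random.default_rng(11)
    p = ParameterSet()
    v_sum = p.v5 * 2  # FTc has two additive activation terms
    for _ in range(200):
        regs = {k: rng.uniform(0, 1e3) for k in ZERO_REGS}
        for gene in MODELED_GENES:
            s = synthesis_rate(MC, gene, p, regs)
            cap = v_sum if gene == "FTc" else p.get(f"v{MODELED_GENES.index(gene)+1}")
            assert 0.0 <= s <= cap + 1e-12


# ---------------------------------------------------------------------------
# genotype handling
# ---------------------------------------------------------------------------

def test_apply_genotype(mech_dataset):
    assert apply_genotype(mech_dataset, genotype_spec("WT")) is mech_dataset
    gig = genotype_spec("gigas-2")
    clamped = apply_genotype(mech_dataset, gig)
    fta1 = clamped.frame[clamped.frame["gene"] == "FTa1"]
    assert (fta1["mean"] == 0).all()
    again = apply_genotype(clamped, gig)
    assert (again.frame["mean"] == clamped.frame["mean"]).all()  # idempotent
    with pytest.raises(ConfigurationError):
        genotype_spec("nonesuch")


# ---------------------------------------------------------------------------
# simulation vs closed form
# ---------------------------------------------------------------------------

def test_closed_form_examples():
    zero = (np.array([0.0, 30.0]), np.array([0.0, 0.0]))
    tr = closed_form_solution(zero, lam=1.0, u0=1.0, t_grid=[0.0, np.log(2.0)])
    assert tr.values[-1] == pytest.approx(0.5, rel=1e-12)
    const = (np.array([0.0, 500.0]), np.array([2.0, 2.0]))
    tr = closed_form_solution(const, lam=0.2, u0=0.0, t_grid=[0.0, 400.0])
    assert tr.values[-1] == pytest.approx(2.0 / 0.2, rel=1e-10)  # steady state s/lam


def test_closed_form_against_adaptive_quadrature():
    rng = np.random.default_rng(5)
    for _ in range(5):
        times = np.sort(rng.uniform(0, 30, 6))
        vals = rng.uniform(0, 5, 6)
        lam = rng.uniform(0.05, 1.0)
        u0 = rng.uniform(0, 3)
        t_end = times[-1]
        tr = closed_form_solution((times, vals), lam, u0, [times[0], t_end])
        integral, _ = quad(
            lambda s: np.exp(-lam * (t_end - s)) * np.interp(s, times, vals),
            times[0], t_end, limit=400, epsabs=1e-12, epsrel=1e-12,
            points=times[1:-1])
        want = u0 * np.exp(-lam * (t_end - times[0])) + integral
        assert tr.values[-1] == pytest.approx(want, abs=1e-9)


def test_simulate_constant_regulators_closed_form(mech_dataset):
    """With constant synthesis s the solution is u0*e^-lt + (s/l)(1-e^-lt)."""
    p = ParameterSet(v4=1.3, K9=2.0, lam=0.199)
    # LF with zero FTb2 input: synthesis is exactly v4 (repression term = 1)
    frame = mech_dataset.frame.copy()
    frame.loc[frame["gene"] == "FTb2", "mean"] = 0.0
    from flornet.data_model import ExpressionDataset
    ds = ExpressionDataset(frame)
    t = np.arange(7.0, 35.1, 3.5)
    got = simulate_gene(model_spec("MC"), "LF", p, ds, WT_LD, t)
    u0 = ds.series("LF", "apex", WT_LD).values[0]
    want = u0 * np.exp(-p.lam * (t - 7)) + (p.v4 / p.lam) * (1 - np.exp(-p.lam * (t - 7)))
    assert np.allclose(got.values, want, rtol=1e-6)


def test_simulate_matches_closed_form_on_random_draws(mech_dataset):
    """Adaptive solver and integrating-factor oracle agree to <= 1e-6."""
    regs = DataRegulators(mech_dataset, WT_LD)
    rng = np.random.default_rng(21)
    t_grid = np.arange(7.0, 35.1, 1.0)
    fine = np.arange(7.0, 35.0 + 0.01, 0.01)
    worst = 0.0
    for i in range(50):
        kw = {f"v{j}": rng.uniform(0.2, 3) for j in range(1, 7)}
        kw.update({f"K{j}": rng.uniform(0.3, 8) for j in range(1, 13)})
        p = ParameterSet(tau=rng.uniform(0, 7), **kw)
        gene = MODELED_GENES[i % 6]
        sim = simulate_gene(MC, gene, p, mech_dataset, WT_LD, t_grid)
        s = synthesis_rate(MC, gene, p, regs.at(fine, p, MC.binding_mode))
        oracle = closed_form_solution((fine, s), p.lam, regs.initial_value(gene), t_grid)
        scale = max(np.max(np.abs(oracle.values)), 1e-12)
        worst = max(worst, np.max(np.abs(sim.values - oracle.values)) / scale)
    assert worst <= 1e-6


def test_gigas2_pim_trajectory_near_zero():
    """In the FTa1 null the PIM activator vanishes, so PIM stays ~0."""
    from flornet.synthetic_data import generate_mechanistic
    ds = generate_mechanistic(MC, conditions=[ConditionKey("gigas-2", "LD")])
    t = np.arange(7.0, 56.1, 7.0)
    tr = simulate_gene(MC, "PIM", ParameterSet(), ds, ConditionKey("gigas-2", "LD"), t)
    assert np.all(tr.values <= 0.05 + 1e-9)  # decays from its tiny start


def test_fast_method_agrees_with_ivp(mech_dataset):
    from flornet.synthetic_data import TRUE_PARAMS_MC
    t = np.arange(7.0, 35.1, 7.0)
    for gene in MODELED_GENES:
        a = simulate_gene(MC, gene, TRUE_PARAMS_MC, mech_dataset, WT_LD, t, method="ivp")
        b = simulate_gene(MC, gene, TRUE_PARAMS_MC, mech_dataset, WT_LD, t, method="fast")
        assert np.allclose(a.values, b.values, rtol=2e-3, atol=1e-6)
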