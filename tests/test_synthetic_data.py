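import json

import numpy as np
import pandas as pd
import pytest

import comboscreen as cs
from comboscreen.synthetic_data import ExpressionSimConfig


def test_same_seed_gives_byte_identical_matrices(two_drugs):
    cfg = dict(drugs=two_drugs, noise_sd=3.0, n_replicates=2, seed=99)
    a = cs.simulate_screen(cs.ScreenSimConfig(**cfg))
    b = cs.simulate_screen(cs.ScreenSimConfig(**cfg))
    for ma, mb in zip(a.matrices, b.matrices):
        assert ma.to_long().to_csv() == mb.to_long().to_csv()
    c = cs.simulate_screen(cs.ScreenSimConfig(**{**cfg, "seed": 100}))
    assert a.matrices[0].to_long().to_csv() != c.matrices[0].to_long().to_csv()


def test_replicates_differ_only_in_noise(two_drugs):
    res = cs.simulate_screen(
        cs.ScreenSimConfig(drugs=two_drugs, noise_sd=3.0, n_replicates=2, seed=1)
    )
    m1, m2 = res.matrices
    assert not np.allclose(m1.activity, m2.activity)
    np.testing.assert_array_equal(m1.doses_a, m2.doses_a)
    noiseless = cs.simulate_screen(
        cs.ScreenSimConfig(drugs=two_drugs, noise_sd=0.0, n_replicates=2, seed=1)
    )
    np.testing.assert_array_equal(*[m.activity for m in noiseless.matrices])


def test_single_agent_wells_follow_the_hill_curve():
    drug = cs.DrugParams(id="X", a0=0.0, ainf=-100.0, ec50=100.0, hill=1.0)
    assert drug.activity(100.0) == pytest.approx(-50.0)  # midpoint of 0 and -100
    res = cs.simulate_screen(
        cs.ScreenSimConfig(drugs=(drug, drug), noise_sd=0.0, seed=0)
    )
    m = res.matrices[0]
    np.testing.assert_allclose(m.activity[:, 0], drug.activity(m.doses_a))
    np.testing.assert_allclose(m.activity[0, :], drug.activity(m.doses_b))
    assert m.activity[0, 0] == 0.0


def test_noiseless_null_equals_bliss_composite_everywhere(null_screen):
    m = null_screen.matrices[0]
    obs, _ = cs.activity_to_inhibition(m.activity)
    fa, fb = null_screen.truth.fa, null_screen.truth.fb
    np.testing.assert_allclose(
        obs, fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :], atol=1e-12
    )


def test_dose_layout_spans_zero_to_max_inhibition(two_drugs):
    layout = cs.DoseLayout(size=6, dilution=3.0, max_inhibition=0.85)
    doses = layout.doses_for(two_drugs[0])
    assert len(doses) == 6
    assert np.all(np.diff(doses) > 0)
    f = two_drugs[0].inhibition(doses)
    assert f[-1] == pytest.approx(0.85)
    np.testing.assert_allclose(np.diff(doses) / doses[:-1], 2.0)  # 3-fold steps


def test_deviation_is_zero_on_single_agent_wells():
    for kind, amp in (("constant", 0.2), ("gaussian_bump", 0.3), ("zero", 0.0)):
        dev = cs.DeviationSpec(kind=kind, amplitude=amp, center=(10.0, 10.0))
        assert dev(0.0, 5.0) == 0.0
        assert dev(5.0, 0.0) == 0.0
    assert cs.DeviationSpec(kind="constant", amplitude=0.2)(5.0, 5.0) == 0.2
    bump = cs.DeviationSpec(kind="gaussian_bump", amplitude=0.3,
                            center=(10.0, 10.0), width=0.5)
    assert bump(10.0, 10.0) == pytest.approx(0.3)
    assert bump(1000.0, 1000.0) < 0.01


def test_clamped_wells_are_flagged(two_drugs):
    cfg = cs.ScreenSimConfig(
        drugs=two_drugs,
        deviation=cs.DeviationSpec(kind="constant", amplitude=0.5),
        noise_sd=0.0, seed=0,
    )
    res = cs.simulate_screen(cfg)
    assert res.truth.clamped.any()
    clamped = res.truth.clamped
    np.testing.assert_allclose(res.truth.true_inhibition[clamped], 1.0)
    unclamped_combo = (
        ~clamped
        & (res.truth.doses_a[:, None] > 0)
        & (res.truth.doses_b[None, :] > 0)
    )
    np.testing.assert_allclose(res.truth.injected_excess[unclamped_combo], 0.5)


def test_truth_record_round_trips_to_json(tmp_path, null_screen):
    path = tmp_path / "truth.json"
    null_screen.truth.to_json(path)
    payload = json.loads(path.read_text())
    np.testing.assert_allclose(payload["expected"], null_screen.truth.expected)
    assert payload["mean_injected_excess"] == 0.0


def test_config_validation():
    drug = cs.DrugParams(id="X")
    with pytest.raises(ValueError, match="exactly 2"):
        cs.ScreenSimConfig(drugs=(drug,)).validate()
    with pytest.raises(ValueError, match="Ainf"):
        cs.DrugParams(id="X", ainf=-150.0).validate()
    with pytest.raises(ValueError, match="n_replicates"):
        cs.ScreenSimConfig(drugs=(drug, drug), n_replicates=0).validate()
    with pytest.raises(ValueError, match="amplitude"):
        cs.DeviationSpec(kind="constant", amplitude=1.5).validate()
    with pytest.raises(ValueError, match="signature larger"):
        ExpressionSimConfig(n_genes_total=10, n_signature_e=6,
                            n_signature_m=6).validate()


def test_simulate_panel_is_deterministic_and_targets_deviation(two_drugs):
    anchor = cs.DrugParams(id="anchor")
    partners = [cs.DrugParams(id=f"P{i}") for i in range(3)]
    devs = {"P1": cs.DeviationSpec(kind="constant", amplitude=0.2)}
    kw = dict(noise_sd=0.0, n_replicates=1, seed=5)
    a = cs.simulate_panel(anchor, partners, devs, **kw)
    b = cs.simulate_panel(anchor, partners, devs, **kw)
    for pid in a:
        assert a[pid].matrices[0].to_long().to_csv() == b[pid].matrices[0].to_long().to_csv()
    assert a["P1"].truth.mean_injected_excess > 0
    assert a["P0"].truth.mean_injected_excess == 0.0


def test_expression_simulation_block_structure():
    res = cs.simulate_expression(
        ExpressionSimConfig(effect_size=3.0, noise_sd=0.0,
                            n_samples_per_phenotype=4, seed=8)
    )
    assert res.matrix.shape == (1000, 8)
    assert len(res.signature.epithelial) == 25
    assert len(res.signature.mesenchymal) == 52
    m_samples = [s for s, l in res.labels.items() if l == "mesenchymal"]
    e_samples = [s for s, l in res.labels.items() if l == "epithelial"]
    m_gene = res.signature.mesenchymal[0]
    # mesenchymal marker sits 2 x effect_size higher in mesenchymal samples
    gap = (res.matrix.loc[m_gene, m_samples].mean()
           - res.matrix.loc[m_gene, e_samples].mean())
    assert gap == pytest.approx(6.0)


def test_zero_effect_size_gives_no_separation():
    res = cs.simulate_expression(
        ExpressionSimConfig(effect_size=0.0, noise_sd=0.5, seed=3)
    )
    results, _ = cs.score_matrix_emt(res.matrix, res.signature)
    acc = np.mean([r.phenotype == res.labels[r.sample_id] for r in results])
    assert 0.2 <= acc <= 0.8  # chance-level recovery only


def test_expression_determinism():
    cfg = ExpressionSimConfig(seed=11)
    a = cs.simulate_expression(cfg).matrix
    b = cs.simulate_expression(cfg).matrix
    pd.testing.assert_frame_equal(a, b)


def test_tumor_growth_noiseless_caliper_inversion():
    table = cs.simulate_tumor_growth(
        groups={"g": 1}, growth_rates={"g": 0.0},
        start_volume=180.0, days=[0.0], noise_sd=0.0, seed=0,
    )
    row = table.iloc[0]
    assert row["length_mm"] == pytest.approx(10.0)
    assert row["width_mm"] == pytest.approx(6.0)
    assert row["length_mm"] * row["width_mm"] ** 2 == pytest.approx(360.0)


def test_tumor_growth_validation_and_determinism():
    with pytest.raises(ValueError, match="start_volume"):
        cs.simulate_tumor_growth({"g": 1}, {"g": 0.1}, start_volume=0.0)
    with pytest.raises(ValueError, match="growth rate missing"):
        cs.simulate_tumor_growth({"g": 1}, {})
    a = cs.simulate_tumor_growth({"g": 3}, {"g": 0.1}, noise_sd=0.1, seed=4)
    b = cs.simulate_tumor_growth({"g": 3}, {"g": 0.1}, noise_sd=0.1, seed=4)
    pd.testing.assert_frame_equal(a, b)
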