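import numpy as np
import pytest
from scipy import stats

import clonetrack as ct
from clonetrack.synthetic_data import SimParams, build_scenario, emit_scenario


SMALL = dict(
    k_true=5, m=400, n_library_cultivars=10, n_library_accessions=16,
    n_library_founders=4, n_released=4, n_field_library_clones=40,
    n_field_nonlibrary_clones=10, n_nonlibrary_genets=3, n_f1=10,
    n_backcross=5, n_multi=5,
)


def test_founder_frequencies_follow_beta():
    # sample size chosen so the fixation clamp at 1e-3 (≈2 % of Beta(0.5,0.5)
    # mass moved to the boundary) stays below the KS resolution
    F = ct.simulate_founders(2, 500, rng=7)
    ks = stats.kstest(F.ravel(), stats.beta(0.5, 0.5).cdf)
    assert ks.pvalue > 0.01
    assert F.min() >= 1e-3 and F.max() <= 1 - 1e-3


def test_founders_deterministic_and_single():
    assert np.array_equal(ct.simulate_founders(3, 50, rng=5),
                          ct.simulate_founders(3, 50, rng=5))
    assert ct.simulate_founders(1, 10, rng=0).shape == (1, 10)


def test_genotype_moments_match_design():
    """Pure samples from founder k have per-locus dosage mean ~ 2 f_kj."""
    rng = np.random.default_rng(17)
    F = ct.simulate_founders(2, 50, rng=rng)
    Q = np.tile([1.0, 0.0], (500, 1))
    G = ct.simulate_genotypes(F, Q, rng=rng)
    mean = G.dosage.mean(axis=0)
    se = np.sqrt(2 * F[0] * (1 - F[0]) / 500)
    assert (np.abs(mean - 2 * F[0]) < 5 * np.maximum(se, 1e-3)).all()


def test_genotype_limit_all_alt():
    F = np.full((1, 30), 1.0 - 1e-9)
    G = ct.simulate_genotypes(F, np.ones((5, 1)), rng=1)
    assert (G.dosage == 2).all()


def test_heterozygosity_matches_hwe():
    rng = np.random.default_rng(23)
    F = ct.simulate_founders(1, 2000, rng=rng)
    G = ct.simulate_genotypes(F, np.ones((200, 1)), rng=rng)
    h_obs = (G.dosage == 1).mean(axis=0)
    h_exp = 2 * F[0] * (1 - F[0])
    assert np.abs(h_obs.mean() - h_exp.mean()) < 0.01


def test_clonal_copies_exact_without_error(rng):
    F = ct.simulate_founders(2, 300, rng=rng)
    G = ct.simulate_genotypes(F, np.eye(2), rng=rng)
    aug, meta = ct.make_clonal_copies(G, [G.sample_ids[0]], 2, 0.0, 0.0, seed=1)
    D = ct.ibs_distance(aug)
    i = aug.sample_index(G.sample_ids[0])
    for m in meta:
        assert D.d[i, aug.sample_index(m.sample_id)] == 0.0
        assert m.duplicate_group == G.sample_ids[0]


def test_clonal_copy_distance_matches_closed_form():
    """Copy-vs-source IBS distance has expectation eps * H / 2 (each miscalled
    het moves the dosage by 1, i.e. contributes 1/2 to the per-locus term)."""
    rng = np.random.default_rng(29)
    m, eps, reps = 4000, 0.06, 30
    F = ct.simulate_founders(1, m, rng=rng)
    G = ct.simulate_genotypes(F, np.ones((1, 1)), rng=rng)
    H = (G.dosage[0] == 1).mean()
    dists = []
    for r in range(reps):
        aug, meta = ct.make_clonal_copies(G, [G.sample_ids[0]], 1, eps, 0.0, seed=100 + r)
        D = ct.ibs_distance(aug)
        dists.append(D.d[0, 1])
    expected = eps * H / 2
    se = np.sqrt(expected * (1 - expected) / (m * reps)) + 1e-9
    assert np.mean(dists) == pytest.approx(expected, abs=4 * se)


def test_two_copies_pairwise_distance():
    """Two independent noisy copies differ where exactly one of them miscalls
    a het: expected distance ~ 2 (eps H / 2)(1 - eps/2) to first order."""
    rng = np.random.default_rng(31)
    m, eps = 4000, 0.06
    F = ct.simulate_founders(1, m, rng=rng)
    G = ct.simulate_genotypes(F, np.ones((1, 1)), rng=rng)
    H = (G.dosage[0] == 1).mean()
    dists = []
    for r in range(30):
        aug, meta = ct.make_clonal_copies(G, [G.sample_ids[0]], 2, eps, 0.0, seed=200 + r)
        D = ct.ibs_distance(aug)
        dists.append(D.d[1, 2])
    # per het locus: both copies flip w.p. eps^2 (distance 0 or 1 for opposite
    # homozygotes), exactly one flips w.p. 2 eps (1-eps) giving 1/2
    expected = H * (2 * eps * (1 - eps) * 0.5 + eps**2 * 0.5)
    assert np.mean(dists) == pytest.approx(expected, rel=0.15)


def test_scenario_truth_bookkeeping():
    sc = build_scenario(SimParams(**SMALL, seed=42))
    assert sc.G.n_samples == len(sc.truth.sample_ids) == len(sc.meta)
    cats = set(sc.truth.category.values())
    assert cats == {
        "library", "field_library_clone", "field_nonlibrary_clone",
        "f1", "backcross", "multi",
    }
    # every sample in exactly one category, Q rows on the simplex
    assert sorted(sc.truth.category) == sorted(sc.G.sample_ids)
    assert np.allclose(sc.truth.Q.sum(axis=1), 1.0)
    # library samples: accessions in duplicate
    lib = [m for m in sc.meta if m.source == "library"]
    assert len(lib) == SMALL["n_library_accessions"] * 2
    groups = {}
    for m in lib:
        groups.setdefault(m.duplicate_group, []).append(m.sample_id)
    assert all(len(v) == 2 for v in groups.values())
    # hybrid truth matches design fractions
    for sid, cat in sc.truth.category.items():
        q = sc.truth.q_of(sid)
        if cat == "f1":
            assert sorted(q[q > 0]) == [0.5, 0.5]
        elif cat == "backcross":
            assert sorted(q[q > 0]) == [0.25, 0.75]
        elif cat == "multi":
            assert q.max() < 0.5


def test_no_multi_when_disabled():
    params = SimParams(**{**SMALL, "n_multi": 0}, seed=1)
    sc = build_scenario(params)
    assert "multi" not in set(sc.truth.category.values())


def test_emit_scenario_files_deterministic(tmp_path):
    params = SimParams(**SMALL, seed=9)
    p1 = emit_scenario(params, tmp_path / "a")
    p2 = emit_scenario(params, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()
    G = ct.read_genotype_table(p1["genotypes"])
    meta = ct.read_sample_metadata(p1["metadata"])
    assert G.n_samples == len(meta)


def test_field_survey_pipeline_end_to_end(tmp_path):
    """Scaled-down field-survey scenario runs through the full pipeline:
    QC -> calibration -> collapse -> matching -> supervised ancestry ->
    classification -> report."""
    params = SimParams(**SMALL, seed=3)
    paths = emit_scenario(params, tmp_path)
    G = ct.read_genotype_table(paths["genotypes"])
    meta = ct.read_sample_metadata(paths["metadata"])
    G, _ = ct.filter_loci(G)
    lib_ids = [m.sample_id for m in meta if m.source == "library"]
    fld_ids = [m.sample_id for m in meta if m.source == "field"]
    G_lib, G_fld = G.subset(samples=lib_ids), G.subset(samples=fld_ids)
    t = ct.calibrate_threshold(ct.ibs_distance(G_lib), meta)
    lib = ct.collapse_library(G_lib, t, meta)
    assert len(lib) == SMALL["n_library_cultivars"]
    assign = ct.match_to_library(G_fld, lib, t)
    fit = ct.fit_admixture(G_fld, params.k_true, seed=5, n_restarts=1,
                           tol=1e-4, max_iter=200)
    classes = ct.classify_ancestry(fit.Q)
    report = ct.build_variety_report(assign, classes, G_fld.sample_ids, lib, meta)
    assert report.summary["n_accessions"].sum() == len(fld_ids)
    corr = ct.name_correspondence(report.accessions, min_name_count=1)
    assert corr.table.to_numpy().sum() > 0
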