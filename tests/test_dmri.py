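"""Diffusion and relaxometry model fits."""

import numpy as np
import pytest
from scipy.integrate import quad

import fibrefuse.dmri as dm
from fibrefuse.gradients import GradientScheme, generate_directions
from fibrefuse.phantom import build_fibre_field, simulate_dwi
from fibrefuse.sphere import axial_angle_deg


def dwi_from_signal(sig, scheme, **kw):
    return dm.DWIVolume(np.asarray(sig)[None, None, None, :], scheme, **kw)


# ------------------------------------------------------------ preprocessing

def test_drift_correction_hand_computed_line():
    sch = GradientScheme(np.zeros((3, 3)), [0.0, 0.0, 0.0])
    data = np.array([100.0, 98.0, 96.0])
    dwi = dwi_from_signal(data, sch, s0_times=np.array([0.0, 1.0, 2.0]))
    out = dm.correct_drift(dwi)
    assert np.allclose(out.data[0, 0, 0], 100.0)


def test_drift_correction_identity_without_drift():
    sch = GradientScheme(np.zeros((2, 3)), [0.0, 0.0])
    dwi = dwi_from_signal([50.0, 50.0], sch, s0_times=np.array([0.0, 5.0]))
    assert np.allclose(dm.correct_drift(dwi).data, dwi.data)


def test_drift_correction_round_trip(scheme60):
    f = build_fibre_field("single", shape=(2, 2, 1))
    clean = simulate_dwi(f, scheme60)
    # apply a 5% linear drift over the acquisition, anchored at two b0s
    sch2 = GradientScheme(
        np.vstack([scheme60.directions, np.zeros(3)]),
        np.r_[scheme60.bvals, 0.0],
    )
    data = np.concatenate([clean.data, clean.data[..., :1]], axis=-1)
    n = data.shape[-1]
    t = np.linspace(0, 1, n)
    drift = 1.0 - 0.05 * t
    dwi = dm.DWIVolume(data * drift, sch2, s0_times=np.array([t[0], t[-1]]))
    out = dm.correct_drift(dwi)
    assert np.max(np.abs(out.data / data - 1)) < 1e-6


def test_drift_requires_two_b0s():
    sch = GradientScheme(np.array([[1.0, 0, 0]]), [4.0])
    with pytest.raises(ValueError):
        dm.correct_drift(dwi_from_signal([1.0], sch))


def test_normalise_s0():
    sch = GradientScheme(np.vstack([np.zeros(3), [1.0, 0, 0]]), [0.0, 4.0])
    data = np.zeros((2, 1, 1, 2))
    data[0, 0, 0] = [2.0, 1.0]
    data[1, 0, 0] = [0.0, 1.0]  # zero reference voxel
    out = dm.normalise_s0(dm.DWIVolume(data, sch))
    assert out.data[0, 0, 0, 0] == pytest.approx(1.0)
    assert out.data[0, 0, 0, 1] == pytest.approx(0.5)
    assert not out.mask[1, 0, 0]
    assert out.n_zero_reference == 1


# ----------------------------------------------------------------------- DTI

def test_dti_isotropic(scheme60):
    f = build_fibre_field("single", shape=(2, 1, 1), fraction=0.0, diffusivity=0.5)
    tm = dm.fit_dti(simulate_dwi(f, scheme60))
    assert tm.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
    assert tm.md[0, 0, 0] == pytest.approx(0.5, abs=1e-9)


def test_dti_recovers_random_spd_tensor(scheme60):
    rng = np.random.default_rng(3)
    a = rng.standard_normal((3, 3))
    dmat = a @ a.T / 6 + 0.3 * np.eye(3)
    b, g = scheme60.bvals, scheme60.directions
    sig = 2.0 * np.exp(-b * np.einsum("ni,ij,nj->n", g, dmat, g))
    tm = dm.fit_dti(dwi_from_signal(sig, scheme60))
    assert np.allclose(tm.tensor[0, 0, 0], dmat, atol=1e-8)
    assert tm.s0[0, 0, 0] == pytest.approx(2.0, abs=1e-8)


def test_dti_fa_one_for_rank_one_tensor(scheme60):
    dmat = np.diag([1.0, 1e-9, 1e-9])
    b, g = scheme60.bvals, scheme60.directions
    sig = np.exp(-b * np.einsum("ni,ij,nj->n", g, dmat, g))
    tm = dm.fit_dti(dwi_from_signal(sig, scheme60))
    assert tm.fa[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
    assert abs(tm.v1[0, 0, 0] @ np.array([1.0, 0, 0])) == pytest.approx(1.0, abs=1e-6)


def test_dti_needs_six_directions():
    sch = GradientScheme(np.vstack([np.zeros(3), np.eye(3)]),
                         [0.0, 4.0, 4.0, 4.0])
    with pytest.raises(ValueError):
        dm.fit_dti(dwi_from_signal(np.ones(4), sch))


# ----------------------------------------------------------- Ball and Stick

def test_bas_single_stick_round_trip(scheme60):
    f = build_fibre_field("single", shape=(1, 1, 1), fraction=0.6, angle=30.0)
    bas = dm.fit_ball_and_stick(simulate_dwi(f, scheme60), n_samples=0, seed=0)
    assert bas.n_pops[0] == 1
    truth = np.array([np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0])
    assert axial_angle_deg(bas.axes[0, 0], truth) < 0.5
    assert 0.59 <= bas.fractions[0, 0] <= 0.61


def test_bas_pure_ball_selects_no_population(scheme60):
    f = build_fibre_field("single", shape=(1, 1, 1), fraction=0.0, diffusivity=0.4)
    bas = dm.fit_ball_and_stick(simulate_dwi(f, scheme60), n_samples=0, seed=0)
    assert bas.n_pops[0] == 0


def test_bas_invariant_to_gradient_sign_flip(scheme60):
    f = build_fibre_field("single", shape=(1, 1, 1), fraction=0.6, angle=40.0)
    dwi = simulate_dwi(f, scheme60)
    flipped = GradientScheme(-scheme60.directions, scheme60.bvals)
    dwi2 = dm.DWIVolume(dwi.data, flipped)
    a1 = dm.fit_ball_and_stick(dwi, n_samples=0, seed=0).axes[0, 0]
    a2 = dm.fit_ball_and_stick(dwi2, n_samples=0, seed=0).axes[0, 0]
    assert axial_angle_deg(a1, a2) < 1e-3


def test_bas_bootstrap_samples_have_unit_norm(scheme60):
    f = build_fibre_field("single", shape=(1, 1, 1), fraction=0.6)
    dwi = simulate_dwi(f, scheme60, noise_sigma=0.03, seed=4)
    bas = dm.fit_ball_and_stick(dwi, n_samples=10, seed=1)
    s = bas.samples[0, 0]
    assert np.allclose(np.linalg.norm(s, axis=-1), 1.0, atol=1e-8)


def test_bas_voxel_lookup(scheme60):
    f = build_fibre_field("single", shape=(2, 1, 1), fraction=0.6)
    bas = dm.fit_ball_and_stick(simulate_dwi(f, scheme60), n_samples=0, seed=0)
    fr, samples = bas.voxel((0, 0, 0))
    assert len(fr) == 1 and samples.shape[-1] == 3
    assert bas.voxel((9, 9, 9)) is None


# ------------------------------------------------------ orientation precision

def test_precision_identical_and_isotropic_samples():
    same = np.tile([0.0, 0.0, 1.0], (10, 1))
    assert dm.orientation_precision(same) == pytest.approx(0.0, abs=1e-6)
    rng = np.random.default_rng(0)
    v = rng.standard_normal((50_000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    got = dm.orientation_precision(v)
    assert got == pytest.approx(np.degrees(np.arccos(np.sqrt(1 / 3))), abs=1.0)
    with pytest.raises(ValueError):
        dm.orientation_precision(np.array([[0.0, 0, 1.0]]))


def test_precision_matches_watson_integral_oracle():
    """Sampled Watson axes match the closed-form dyadic statistic."""
    kappa = 8.0
    rng = np.random.default_rng(5)
    # rejection-sample Watson axes about z
    v = rng.standard_normal((200_000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    keep = rng.uniform(size=len(v)) < np.exp(kappa * (v[:, 2] ** 2 - 1.0))
    v = v[keep][:20_000]
    got = dm.orientation_precision(v)
    # oracle: E[cos^2 theta] under the Watson density by numerical quadrature
    num = quad(lambda t: np.cos(t) ** 2 * np.exp(kappa * np.cos(t) ** 2)
               * np.sin(t), 0, np.pi)[0]
    den = quad(lambda t: np.exp(kappa * np.cos(t) ** 2) * np.sin(t), 0, np.pi)[0]
    expected = np.degrees(np.arccos(np.sqrt(num / den)))
    assert got == pytest.approx(expected, rel=0.05)


# --------------------------------------------------------- Ball and Rackets

def test_bar_recovers_bingham_concentrations(scheme60):
    from fibrefuse.sphere import symmetric_sphere_grid

    grid = symmetric_sphere_grid(256)
    b, g = scheme60.bvals, scheme60.directions
    w = dm.bingham_weights(np.pi / 2, 0.0, 0.3, 4.0, 16.0, grid)
    gd2 = (g @ grid.T) ** 2
    sig = (1 - 0.7) * np.exp(-b * 0.4) + 0.7 * (np.exp(-b[:, None] * 0.4 * gd2) @ w)
    bar = dm.fit_ball_and_rackets(dwi_from_signal(sig, scheme60), seed=0)
    assert bar.kappa1[0, 0, 0] == pytest.approx(4.0, rel=0.15)
    assert bar.kappa2[0, 0, 0] == pytest.approx(16.0, rel=0.15)
    assert bar.f[0, 0, 0] == pytest.approx(0.7, abs=0.02)
    assert axial_angle_deg(bar.axis[0, 0, 0], np.array([1.0, 0, 0])) < 1.0


def test_bar_pure_stick_gives_large_concentration(scheme60):
    f = build_fibre_field("single", shape=(1, 1, 1), fraction=0.8, angle=20.0)
    bar = dm.fit_ball_and_rackets(simulate_dwi(f, scheme60), seed=0)
    assert bar.kappa2[0, 0, 0] > 50.0
    truth = np.array([np.cos(np.radians(20)), np.sin(np.radians(20)), 0.0])
    assert axial_angle_deg(bar.axis[0, 0, 0], truth) < 1.0


# ----------------------------------------------------------------- DIVIDE

def divide_schemes(dirs60):
    bshells = [0.5, 1.0, 1.5, 2.0]
    lin_dirs = np.vstack([np.zeros(3)] + [dirs60 for _ in bshells])
    lin_b = np.r_[0.0, np.concatenate([np.full(60, b) for b in bshells])]
    sph_b = np.r_[0.0, bshells]
    lin = GradientScheme(lin_dirs, lin_b)
    sph = GradientScheme(np.zeros((len(sph_b), 3)), sph_b,
                         ["spherical"] * len(sph_b))
    return lin, sph


def test_divide_isotropic_system_has_zero_ufa(dirs60):
    lin, sph = divide_schemes(dirs60)
    s_lin = np.exp(-lin.bvals * 1.0)
    s_sph = np.exp(-sph.bvals * 1.0)
    maps = dm.fit_divide(dwi_from_signal(s_lin, lin), dwi_from_signal(s_sph, sph))
    assert maps.ufa[0, 0, 0] < 0.02


def test_divide_gamma_self_consistency(dirs60):
    lin, sph = divide_schemes(dirs60)
    mu1, m2l, m2s = 0.8, 0.15, 0.05
    s_lin = (1 + lin.bvals * m2l / mu1) ** (-mu1**2 / m2l)
    s_sph = (1 + sph.bvals * m2s / mu1) ** (-mu1**2 / m2s)
    maps = dm.fit_divide(dwi_from_signal(s_lin, lin), dwi_from_signal(s_sph, sph))
    assert maps.md[0, 0, 0] == pytest.approx(mu1, abs=1e-6)
    assert maps.mu2_linear[0, 0, 0] == pytest.approx(m2l, abs=1e-6)
    assert maps.mu2_spherical[0, 0, 0] == pytest.approx(m2s, abs=1e-6)
    assert 0.0 <= maps.ufa[0, 0, 0] <= 1.0


def test_divide_invariant_to_direction_relabelling(dirs60):
    lin, sph = divide_schemes(dirs60)
    rng = np.random.default_rng(0)
    s_lin = np.exp(-lin.bvals * 0.7) * (1 + 0.01 * rng.standard_normal(len(lin)))
    s_sph = np.exp(-sph.bvals * 0.7)
    perm = np.r_[0, 1 + rng.permutation(len(lin) - 1)]
    lin2 = GradientScheme(lin.directions[perm], lin.bvals[perm])
    m1 = dm.fit_divide(dwi_from_signal(s_lin, lin), dwi_from_signal(s_sph, sph))
    m2 = dm.fit_divide(dwi_from_signal(s_lin[perm], lin2),
                       dwi_from_signal(s_sph, sph))
    # identical up to optimiser tolerance (summation order differs)
    assert m1.md[0, 0, 0] == pytest.approx(m2.md[0, 0, 0], rel=1e-3)
    assert m1.ufa[0, 0, 0] == pytest.approx(m2.ufa[0, 0, 0], abs=1e-3)


# ---------------------------------------------------------------------- T1

def test_t1_closed_form_null_crossing():
    a, b, t1 = 1.0, -2.0, 500.0
    tis = np.geomspace(10, 6000, 12)
    sig = a + b * np.exp(-tis / t1)
    assert a + b == pytest.approx(-1.0)                      # S(0)
    ti_null = t1 * np.log(2)
    assert a + b * np.exp(-ti_null / t1) == pytest.approx(0.0, abs=1e-12)
    maps = dm.fit_t1(sig[None, :], tis)
    assert maps.t1[0] == pytest.approx(t1, rel=1e-6)
    assert maps.a[0] == pytest.approx(a, rel=1e-6)           # TI -> inf asymptote
    assert maps.b[0] == pytest.approx(b, rel=1e-6)


def test_t1_round_trip_grid_of_parameters():
    tis = np.geomspace(10, 6000, 12)
    rng = np.random.default_rng(2)
    for _ in range(5):
        a = rng.uniform(0.5, 2.0)
        b = -a * rng.uniform(1.6, 2.0)
        t1 = rng.uniform(200, 2500)
        sig = a + b * np.exp(-tis / t1)
        maps = dm.fit_t1(sig[None, :], tis)
        assert maps.t1[0] == pytest.approx(t1, rel=1e-6)


def test_t1_requires_three_tis():
    with pytest.raises(ValueError):
        dm.fit_t1(np.ones((1, 2)), np.array([10.0, 100.0]))


def test_fits_invariant_to_global_rescaling(scheme60):
    f = build_fibre_field("single", shape=(1, 1, 1), fraction=0.6, angle=30.0)
    dwi = simulate_dwi(f, scheme60)
    scaled = dm.DWIVolume(10.0 * dwi.data, scheme60)
    t1 = dm.fit_dti(dwi)
    t2 = dm.fit_dti(scaled)
    assert t2.fa[0, 0, 0] == pytest.approx(t1.fa[0, 0, 0], abs=1e-10)
    assert t2.md[0, 0, 0] == pytest.approx(t1.md[0, 0, 0], abs=1e-10)
    assert t2.s0[0, 0, 0] == pytest.approx(10 * t1.s0[0, 0, 0], rel=1e-8)
    b1 = dm.fit_ball_and_stick(dwi, n_samples=0, seed=0)
    b2 = dm.fit_ball_and_stick(scaled, n_samples=0, seed=0)
    assert b2.fractions[0, 0] == pytest.approx(b1.fractions[0, 0], abs=1e-6)
    assert b2.d[0] == pytest.approx(b1.d[0], abs=1e-6)


def test_save_bas_samples_nifti(tmp_path, scheme60):
    import json as _json

    import nibabel as nib

    f = build_fibre_field("single", shape=(2, 1, 1), fraction=0.6)
    dwi = simulate_dwi(f, scheme60, noise_sigma=0.02, seed=3)
    bas = dm.fit_ball_and_stick(dwi, n_samples=5, seed=1)
    path = tmp_path / "samples.nii"
    dm.save_bas_samples(bas, path)
    img = nib.load(str(path))
    assert img.shape == (2, 1, 1, 3, 15)
    vol = np.asarray(img.dataobj)
    assert np.allclose(vol[0, 0, 0, 0].reshape(5, 3), bas.samples[0, 0],
                       atol=1e-6)
    side = _json.loads((tmp_path / "samples.nii.json").read_text())
    assert side["n_samples"] == 5
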