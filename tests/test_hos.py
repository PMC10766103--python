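"""Cumulant, bispectrum, principal-domain and band-energy unit tests.

Every estimator is checked against an independent brute-force oracle:
triple loops for the cumulant, literal double sums for the Fourier
transform, exhaustive inequality enumeration for the region masks.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfbispec.hos import (
    HOSConfig,
    bispectrum_direct_oracle,
    bispectrum_indirect,
    estimate_c3,
    principal_domain,
    region_energy,
    segment_features,
    subdivide_bands,
)

from conftest import qpc_segment


def brute_c3(x, L):
    """Triple-loop evaluation of the defining cumulant sum (1/N norm)."""
    N = len(x)
    out = np.zeros((2 * L + 1, 2 * L + 1))
    for k in range(-L, L + 1):
        for l in range(-L, L + 1):
            s = 0.0
            for n in range(N):
                if 0 <= n + k < N and 0 <= n + l < N:
                    s += x[n] * x[n + k] * x[n + l]
            out[k + L, l + L] = s / N
    return out


class TestCumulant:
    def test_zero_segment_gives_zero_lattice(self):
        lat = estimate_c3(np.zeros(256), 16)
        assert np.all(lat.values == 0)

    def test_lag_exchange_symmetry(self, rng):
        lat = estimate_c3(rng.standard_normal(128), 20)
        assert lat.at(3, 5) == pytest.approx(lat.at(5, 3), abs=1e-15)
        assert np.allclose(lat.values, lat.values.T, atol=1e-14)

    @pytest.mark.parametrize("demean", [False, True])
    @pytest.mark.parametrize("n,L", [(32, 7), (64, 15)])
    def test_matches_triple_loop_oracle(self, rng, n, L, demean):
        x = rng.standard_normal(n)
        xe = x - x.mean() if demean else x
        lat = estimate_c3(x, L, demean=demean)
        assert np.allclose(lat.values, brute_c3(xe, L), atol=1e-12)

    def test_small_handworked_segment(self):
        # segment [1, 2, -1, 3], mean subtraction off, max_lag 1
        x = np.array([1.0, 2.0, -1.0, 3.0])
        lat = estimate_c3(x, 1, demean=False)
        assert np.allclose(lat.values, brute_c3(x, 1), atol=1e-14)

    def test_max_lag_validation(self):
        with pytest.raises(ValueError):
            estimate_c3(np.ones(16), 16)


class TestBispectrum:
    def test_zero_lattice_gives_zero_grid(self):
        lat = estimate_c3(np.zeros(64), 8)
        grid = bispectrum_indirect(lat, 32)
        assert np.all(grid.values == 0)

    @pytest.mark.parametrize("n,L,nfft", [(32, 7, 32), (64, 15, 64)])
    def test_matches_double_sum_oracle(self, rng, n, L, nfft):
        """Indirect estimator equals the literal transform on every bin."""
        x = rng.standard_normal(n)
        c3 = estimate_c3(x, L)
        grid = bispectrum_indirect(c3, nfft)
        ks = np.arange(-L, L + 1)
        brute = np.empty((nfft, nfft), complex)
        for i, f1 in enumerate(grid.freqs):
            for j, f2 in enumerate(grid.freqs):
                brute[i, j] = np.sum(
                    c3.values
                    * np.exp(-2j * np.pi * (f1 * ks[:, None] + f2 * ks[None, :]))
                )
        assert np.abs(grid.values - brute).max() < 1e-9

    def test_frequency_exchange_symmetry(self, rng):
        grid = bispectrum_indirect(estimate_c3(rng.standard_normal(128), 15), 64)
        assert np.abs(grid.values - grid.values.T).max() < 1e-10

    def test_nfft_validation(self):
        with pytest.raises(ValueError):
            bispectrum_indirect(estimate_c3(np.ones(64), 15), 16)


class TestDirectOracle:
    def test_zero_signal(self):
        grid = bispectrum_direct_oracle(np.zeros(512), 64, 8)
        assert np.all(grid.values == 0)

    def test_qpc_peak_agrees_with_indirect(self):
        x = qpc_segment(4096, phases=(0.7, 1.9))
        masks = principal_domain(128)
        direct = bispectrum_direct_oracle(x, 128, 16)
        indirect = bispectrum_indirect(estimate_c3(x[:256], 63), 128)
        locs = []
        for grid in (direct, indirect):
            m = np.where(masks.S0, np.abs(grid.values), 0.0)
            locs.append(np.unravel_index(m.argmax(), m.shape))
        assert locs[0] == locs[1]

    def test_gaussian_noise_bispectrum_is_small(self, rng):
        """White Gaussian noise has (asymptotically) zero bispectrum."""
        masks = principal_domain(64)
        x = qpc_segment(64 * 64, phases=(0.3, 1.1))
        x_noise = rng.standard_normal(64 * 64) * np.sqrt(np.mean(x**2))
        peak_qpc = np.abs(
            bispectrum_direct_oracle(x, 64, 64).values[masks.S0]
        ).max()
        peak_noise = np.abs(
            bispectrum_direct_oracle(x_noise, 64, 64).values[masks.S0]
        ).max()
        assert peak_qpc > 10 * peak_noise


class TestRegions:
    def test_principal_domain_definition(self):
        masks = principal_domain(16)
        freqs = np.fft.fftshift(np.fft.fftfreq(16))
        for i, f1 in enumerate(freqs):
            for j, f2 in enumerate(freqs):
                inside = 0 <= f2 <= f1 and f1 + f2 <= 0.5
                assert masks.S0[i, j] == inside

    @pytest.mark.parametrize("nfft", [8, 16])
    def test_cardinality_matches_enumeration(self, nfft):
        masks = principal_domain(nfft)
        freqs = np.fft.fftshift(np.fft.fftfreq(nfft))
        brute = sum(
            1
            for f1 in freqs
            for f2 in freqs
            if 0 <= f2 <= f1 and f1 + f2 <= 0.5
        )
        assert masks.S0.sum() == brute

    @pytest.mark.parametrize("nfft", [16, 64, 128])
    @pytest.mark.parametrize("split_axis", ["f1", "f2"])
    def test_bands_partition_principal_domain(self, nfft, split_axis):
        masks = subdivide_bands(principal_domain(nfft), split_axis=split_axis)
        assert not (masks.S1 & masks.S2).any()
        assert not (masks.S1 & masks.S3).any()
        assert not (masks.S2 & masks.S3).any()
        assert ((masks.S1 | masks.S2 | masks.S3) == masks.S0).all()

    def test_band_edges_are_thirds_of_half(self):
        masks = subdivide_bands(principal_domain(12))
        assert masks.band_edges == (0.0, 1 / 6, 1 / 3, 1 / 2)
        freqs = np.fft.fftshift(np.fft.fftfreq(12))
        f1_in_s1 = sorted({freqs[i] for i, j in zip(*np.nonzero(masks.S1))})
        assert max(f1_in_s1) < 1 / 6

    def test_band_cardinalities_match_enumeration(self):
        nfft = 16
        masks = subdivide_bands(principal_domain(nfft))
        freqs = np.fft.fftshift(np.fft.fftfreq(nfft))
        edges = [0, 1 / 6, 1 / 3, 1 / 2]
        for b, band in enumerate([masks.S1, masks.S2, masks.S3]):
            last = b == 2
            brute = sum(
                1
                for f1 in freqs
                for f2 in freqs
                if 0 <= f2 <= f1
                and f1 + f2 <= 0.5
                and edges[b] <= f1
                and (f1 <= edges[b + 1] if last else f1 < edges[b + 1])
            )
            assert band.sum() == brute


class TestRegionEnergy:
    def test_zero_grid(self):
        masks = principal_domain(16)
        assert region_energy(np.zeros((16, 16)), masks.S0) == 0.0

    def test_all_ones_counts_mask_bins(self):
        mask = np.zeros((16, 16), bool)
        mask.ravel()[:10] = True
        assert region_energy(np.ones((16, 16), complex), mask) == 10.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            region_energy(np.ones((8, 8)), np.ones((4, 4), bool))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), nfft=st.sampled_from([16, 32, 64]))
    def test_partition_identity_random_grids(self, seed, nfft):
        grid = np.random.default_rng(seed).standard_normal(
            (nfft, nfft)
        ) + 1j * np.random.default_rng(seed + 1).standard_normal((nfft, nfft))
        masks = subdivide_bands(principal_domain(nfft))
        parts = sum(
            region_energy(grid, m) for m in (masks.S1, masks.S2, masks.S3)
        )
        whole = region_energy(grid, masks.S0)
        assert parts == pytest.approx(whole, rel=1e-12)


class TestSegmentFeatures:
    def test_zero_segment(self):
        f = segment_features(np.zeros(256))
        assert f.as_array().tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_partition_identity_exact(self, rng):
        f = segment_features(rng.standard_normal(256))
        assert f.E_S1 + f.E_S2 + f.E_S3 == f.E_S0
        assert min(f.as_array()) >= 0

    def test_low_band_coupling_drives_E_S1(self):
        """A pair coupled at (0.12, 0.18) lies in the low-frequency band."""
        f = segment_features(qpc_segment(256, phases=(0.4, 1.3)))
        assert f.E_S1 > f.E_S3

    def test_high_band_coupling_drives_E_S3(self):
        """Coupling at (0.35, 0.05) puts the peak inside the high band."""
        x = qpc_segment(256, f1=0.35, f2=0.05, phases=(0.2, 0.9))
        cfg = HOSConfig()
        f = segment_features(x, cfg)
        assert f.E_S3 > 0
        grid = bispectrum_indirect(estimate_c3(x, cfg.max_lag), cfg.nfft)
        masks = subdivide_bands(principal_domain(cfg.nfft))
        m = np.where(masks.S0, np.abs(grid.values), 0.0)
        i, j = np.unravel_index(m.argmax(), m.shape)
        assert masks.S3[i, j]

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            segment_features(np.ones(100), HOSConfig())


def test_qpc_localization_averaged():
    """The bispectral peak of a coupled triple at (0.12, 0.18, 0.30) lands
    within one bin of the coupled bifrequency (averaged over 64 phase
    realizations on a 128-grid)."""
    cfg = HOSConfig()
    gen = np.random.default_rng(7)
    acc = np.zeros((cfg.nfft, cfg.nfft), complex)
    for _ in range(64):
        phases = gen.uniform(0, 2 * np.pi, 2)
        x = qpc_segment(256, phases=tuple(phases))
        acc += bispectrum_indirect(estimate_c3(x, cfg.max_lag), cfg.nfft).values
    masks = principal_domain(cfg.nfft)
    m = np.where(masks.S0, np.abs(acc), 0.0)
    i, j = np.unravel_index(m.argmax(), m.shape)
    freqs = np.fft.fftshift(np.fft.fftfreq(cfg.nfft))
    # in-S0 representative of the coupled pair has f1 >= f2
    assert abs(freqs[i] - 0.18) <= 1 / cfg.nfft
    assert abs(freqs[j] - 0.12) <= 1 / cfg.nfft
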