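"""Unit and property tests for pattern extraction and the texture transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from virts.core import (
    Pattern,
    TransformConfig,
    compute_K,
    extract_patterns,
    image_to_vector,
    texture_unit,
    vector_geometry,
)
from virts.errors import (
    DegeneratePatternError,
    DimensionError,
    UndefinedDirectionError,
)


def naive_image_to_vector(image, config):
    """Independent oracle: explicit double loop over windows, scalar math."""
    a = np.asarray(image, dtype=float)
    m, n = a.shape
    comps = np.zeros(3)
    n_deg = 0
    for r in range(m - 2):
        for c in range(n - 2):
            p = a[r:r + 3, c:c + 3]
            d = p[0, 0] * p[1, 1] - p[0, 1] * p[1, 0]
            if abs(d) <= config.degeneracy_tol * max(
                    1.0, abs(p[0, 0] * p[1, 1]) + abs(p[0, 1] * p[1, 0])):
                n_deg += 1
                comps[2] += config.lam
                continue
            comps[0] += (p[0, 2] * p[1, 1] - p[1, 2] * p[0, 1]) / d * config.lam
            comps[1] += (p[0, 0] * p[1, 2] - p[1, 0] * p[0, 2]) / d * config.lam
            comps[2] += config.lam
    return comps, (m - 2) * (n - 2), n_deg


int_pixels = st.integers(min_value=0, max_value=255)


def random_pattern_strategy():
    return st.lists(int_pixels, min_size=9, max_size=9).map(
        lambda v: Pattern(np.array(v, dtype=float).reshape(3, 3)))


class TestExtractPatterns:
    @pytest.mark.parametrize("m,n", [(3, 3), (3, 4), (5, 7), (10, 3)])
    def test_count_and_origins(self, m, n, rng):
        img = rng.integers(0, 256, size=(m, n)).astype(float)
        pats = list(extract_patterns(img))
        assert len(pats) == (m - 2) * (n - 2)
        expected_origins = [(r, c) for r in range(m - 2) for c in range(n - 2)]
        assert [p.origin for p in pats] == expected_origins

    def test_values_copied_from_image(self, small_random_image):
        for pat in extract_patterns(small_random_image):
            r, c = pat.origin
            np.testing.assert_array_equal(
                pat.p, small_random_image[r:r + 3, c:c + 3])

    def test_single_window_is_the_image(self):
        img = np.arange(9, dtype=float).reshape(3, 3)
        (pat,) = extract_patterns(img)
        np.testing.assert_array_equal(pat.p, img)
        assert pat.origin == (0, 0)

    def test_too_small_image_rejected(self):
        with pytest.raises(DimensionError):
            list(extract_patterns(np.ones((2, 5))))


class TestComputeK:
    def test_identity_pattern_gives_zero(self):
        assert compute_K(Pattern(np.eye(3))) == 0.0

    def test_singular_matrix_root_finder_oracle(self):
        # independent oracle: solve det(matrix with p33 -> K*p33) = 0 for K
        p = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)

        def det_of_modified(k):
            q = p.copy()
            q[2, 2] = k * p[2, 2]
            return np.linalg.det(q)

        k_oracle = brentq(det_of_modified, -10, 10)
        assert compute_K(Pattern(p)) == pytest.approx(k_oracle, abs=1e-9)
        assert compute_K(Pattern(p)) == pytest.approx(1.0)

    def test_zero_p33_is_degenerate(self):
        p = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 0]], dtype=float)
        with pytest.raises(DegeneratePatternError):
            compute_K(Pattern(p))

    @settings(max_examples=300, derandomize=True)
    @given(random_pattern_strategy())
    def test_modified_matrix_is_singular_wherever_K_defined(self, pat):
        try:
            k = compute_K(pat)
        except DegeneratePatternError:
            return
        q = pat.p.copy()
        q[2, 2] *= k
        scale = max(1.0, float(np.abs(q).max()) ** 3)
        assert abs(np.linalg.det(q)) <= 1e-9 * scale


class TestTextureUnit:
    def test_hand_computed_example(self):
        p = Pattern(np.array([[1, 2, 3], [4, 5, 6], [0, 0, 0]], dtype=float))
        t = texture_unit(p, TransformConfig(lam=2))
        assert (t.t1, t.t2, t.t3) == (-2.0, 4.0, 2.0)
        # both equations of the reduced system hold
        assert 1 * t.t1 + 2 * t.t2 == pytest.approx(3 * t.t3)
        assert 4 * t.t1 + 5 * t.t2 == pytest.approx(6 * t.t3)

    def test_lambda_zero_gives_trivial_solution(self, rng):
        p = Pattern(rng.integers(1, 256, size=(3, 3)).astype(float))
        cfg = TransformConfig(lam=0.0, allow_zero_lambda=True)
        t = texture_unit(p, cfg)
        assert (t.t1, t.t2, t.t3) == (0.0, 0.0, 0.0)

    def test_zero_third_column_gives_pure_t3(self):
        p = Pattern(np.array([[3, 1, 0], [2, 7, 0], [5, 5, 5]], dtype=float))
        t = texture_unit(p, TransformConfig(lam=4))
        assert (t.t1, t.t2, t.t3) == (0.0, 0.0, 4.0)

    def test_flat_pattern_policies(self):
        p = Pattern(np.full((3, 3), 5.0), origin=(7, 9))
        t = texture_unit(p, TransformConfig(lam=2))
        assert (t.t1, t.t2, t.t3, t.degenerate) == (0.0, 0.0, 2.0, True)
        assert texture_unit(p, TransformConfig(degenerate_policy="skip")) is None
        with pytest.raises(DegeneratePatternError) as err:
            texture_unit(p, TransformConfig(degenerate_policy="error"))
        assert err.value.origin == (7, 9)

    @settings(max_examples=500, derandomize=True)
    @given(random_pattern_strategy(),
           st.floats(min_value=0.5, max_value=50, allow_nan=False))
    def test_reduced_system_residual(self, pat, lam):
        """Nondegenerate units satisfy p11 t1 + p12 t2 = p13 t3 (both rows)."""
        t = texture_unit(pat, TransformConfig(lam=lam))
        if t.degenerate:
            return
        p = pat.p
        for row in (0, 1):
            lhs = p[row, 0] * t.t1 + p[row, 1] * t.t2
            rhs = p[row, 2] * t.t3
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9 * max(1, abs(rhs)))


class TestImageToVector:
    def test_single_pattern_image_equals_its_unit(self):
        img = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
        cfg = TransformConfig(lam=2)
        v = image_to_vector(img, cfg)
        t = texture_unit(Pattern(img), cfg)
        np.testing.assert_allclose(v.as_array(), t.as_array())
        assert v.n_patterns == 1

    def test_a3_identity_and_pattern_count(self, rng):
        img = rng.integers(1, 256, size=(30, 41)).astype(float)
        v = image_to_vector(img, TransformConfig(lam=2))
        assert v.n_patterns == 28 * 39
        assert v.a3 == 2 * 28 * 39  # exact under zero-ratio policy

    def test_lambda_linearity(self, small_random_image):
        v2 = image_to_vector(small_random_image, TransformConfig(lam=2))
        v25 = image_to_vector(small_random_image, TransformConfig(lam=25))
        np.testing.assert_allclose(v25.as_array(), (25 / 2) * v2.as_array(),
                                   rtol=1e-12)

    @pytest.mark.parametrize("shape,seed", [((8, 8), 0), ((17, 5), 1),
                                            ((64, 64), 2), ((31, 64), 3)])
    def test_oracle_equivalence_naive_double_loop(self, shape, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=shape).astype(float)
        cfg = TransformConfig(lam=2)
        v = image_to_vector(img, cfg)
        comps, n_pat, n_deg = naive_image_to_vector(img, cfg)
        np.testing.assert_allclose(v.as_array(), comps, rtol=1e-6)
        assert (v.n_patterns, v.n_degenerate) == (n_pat, n_deg)

    def test_skip_policy_drops_degenerate_windows(self):
        img = np.full((5, 5), 9.0)  # every window flat
        v = image_to_vector(img, TransformConfig(lam=2, degenerate_policy="skip"))
        assert v.n_degenerate == 9
        assert v.as_array().tolist() == [0.0, 0.0, 0.0]
        v0 = image_to_vector(img, TransformConfig(lam=2))
        assert v0.a3 == 2 * 9  # zero-ratio keeps the a3 structure

    def test_error_policy_reports_origin(self):
        img = np.arange(25, dtype=float).reshape(5, 5) ** 2
        img[1:4, 1:4] = 7.0  # one flat window at origin (1, 1)
        with pytest.raises(DegeneratePatternError) as err:
            image_to_vector(img, TransformConfig(degenerate_policy="error"))
        assert err.value.origin == (1, 1)


class TestVectorGeometry:
    @pytest.mark.parametrize("v,mag,cosines", [
        ((3, 4, 0), 5.0, (0.6, 0.8, 0.0)),
        ((1, 0, 0), 1.0, (1.0, 0.0, 0.0)),
        ((1, 1, 1), np.sqrt(3), (1 / np.sqrt(3),) * 3),
    ])
    def test_known_vectors(self, v, mag, cosines):
        g = vector_geometry(v)
        assert g.magnitude == pytest.approx(mag)
        np.testing.assert_allclose(
            [g.cos_alpha, g.cos_beta, g.cos_gamma], cosines, rtol=1e-12)

    def test_zero_vector_refused(self):
        with pytest.raises(UndefinedDirectionError):
            vector_geometry((0.0, 0.0, 0.0))

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=3,
                    max_size=3).filter(lambda v: any(abs(x) > 1e-3 for x in v)))
    def test_direction_cosine_squares_sum_to_one(self, v):
        g = vector_geometry(v)
        assert g.cos_alpha ** 2 + g.cos_beta ** 2 + g.cos_gamma ** 2 == \
            pytest.approx(1.0, abs=1e-12)


def test_lambda_zero_requires_explicit_override():
    with pytest.raises(ValueError):
        TransformConfig(lam=0.0)
    cfg = TransformConfig(lam=0.0, allow_zero_lambda=True)
    img = np.arange(16, dtype=float).reshape(4, 4) + 1
    assert image_to_vector(img, cfg).as_array().tolist() == [0.0, 0.0, 0.0]
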