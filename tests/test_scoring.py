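"""Similarity scores: d_img, normalised parameter distances, d_sum, ranking."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmfibril.errors import NormalisationWarning, UndefinedScoreError
from afmfibril.scoring import (
    COMPONENTS,
    CandidateMeasurements,
    MorphometricSet,
    ReferenceFibril,
    combined_score,
    image_distance,
    param_distance,
    rank_candidates,
)
from afmfibril.sections import CrossSection
from afmfibril.tipsim import HeightMap


def _img(arr):
    return HeightMap(heights=np.asarray(arr, dtype=float), pixel_size_nm=1.0)


class TestImageDistance:
    @staticmethod
    def _pair():
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 10, size=(30, 20))
        return _img(data), data

    def test_identical_images_zero(self):
        data, arr = self._pair()
        assert image_distance(data, _img(arr), axis_height_nm=4.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_anticorrelated_images_two(self):
        data, arr = self._pair()
        mask = arr > 4.0
        flipped = arr.copy()
        flipped[mask] = 2 * arr[mask].mean() - arr[mask]
        assert image_distance(data, _img(flipped), 4.0) == pytest.approx(2.0,
                                                                         abs=1e-9)

    def test_matches_pearson_oracle(self):
        # masked vectors [1,2,4] vs [1,2,3]: direct Pearson computation
        data = _img([[1.0, 2.0, 4.0], [0.0, 0.0, 0.0]])
        sim = _img([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        x, y = np.array([1.0, 2, 4]), np.array([1.0, 2, 3])
        r = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        d = image_distance(data, sim, axis_height_nm=0.5)
        assert d == pytest.approx(1 - r, abs=1e-12)
        assert d == pytest.approx(0.018, abs=5e-4)

    def test_empty_mask_rejected(self):
        data, arr = self._pair()
        with pytest.raises(UndefinedScoreError):
            image_distance(data, _img(arr), axis_height_nm=100.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_in_0_2(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 8, size=(10, 8))
        b = rng.uniform(0, 8, size=(10, 8))
        try:
            d = image_distance(_img(a), _img(b), axis_height_nm=2.0)
        except UndefinedScoreError:
            return
        assert -1e-12 <= d <= 2.0 + 1e-12


class TestParamDistance:
    def test_identical_values_zero(self):
        assert param_distance(5.0, 5.0, 3.0) == 0.0

    def test_opposite_handedness_is_one(self):
        # |(+1) - (-1)| / 2 = 1, with the theoretical norm 2 for hnd
        assert param_distance(1, -1, 2.0) == 1.0

    def test_crossover_example(self):
        # candidates {40, 50, 70} vs reference 47.7: norm_max = 22.3
        cands = np.array([40.0, 50.0, 70.0])
        norm = np.max(np.abs(cands - 47.7))
        assert norm == pytest.approx(22.3)
        assert param_distance(50.0, 47.7, norm) == pytest.approx(2.3 / 22.3)

    def test_zero_norm_warns_and_returns_zero(self):
        with pytest.warns(NormalisationWarning):
            assert param_distance(5.0, 5.0, 0.0) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        v=st.floats(-1e3, 1e3), ref=st.floats(-1e3, 1e3),
        extra=st.floats(0.0, 1e3),
    )
    def test_bounded_in_0_1_under_panel_norm(self, v, ref, extra):
        norm = abs(v - ref) + extra
        if norm == 0:
            return
        assert 0.0 <= param_distance(v, ref, norm) <= 1.0


class TestCombinedScore:
    def test_all_zero(self):
        assert combined_score({k: 0.0 for k in COMPONENTS}) == 0.0

    def test_plain_sum(self):
        comp = dict(zip(COMPONENTS, (0.1, 0.0, 0.0, 0.2, 0.3, 0.4)))
        assert combined_score(comp) == pytest.approx(1.0, abs=1e-12)

    def test_missing_component_rejected(self):
        comp = dict(zip(COMPONENTS[:5], [0.1] * 5))
        with pytest.raises(ValueError):
            combined_score(comp)

    def test_negative_component_rejected(self):
        comp = {k: 0.1 for k in COMPONENTS}
        comp["d_cod"] = -0.2
        with pytest.raises(ValueError):
            combined_score(comp)


def _make_reference(seed=0):
    rng = np.random.default_rng(seed)
    data = rng.uniform(0, 8, size=(40, 20))
    t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
    cs = CrossSection(points=np.column_stack([4 * np.cos(t), 2 * np.sin(t)]))
    return ReferenceFibril(
        image=_img(data),
        axis_height_nm=4.0,
        morph=MorphometricSet(sym=2, hnd=-1, cod_nm=47.7, csa_nm2=25.0),
        cross_section=cs,
    )


def _candidate(label, ref, sym=2, hnd=-1, cod=47.7, csa=25.0, csd=0.0,
               img_noise=0.0, seed=1):
    rng = np.random.default_rng(seed)
    sim = ref.image.heights + rng.normal(0, img_noise, ref.image.heights.shape)
    return CandidateMeasurements(
        label=label,
        sim_image=_img(sim),
        morph=MorphometricSet(sym=sym, hnd=hnd, cod_nm=cod, csa_nm2=csa,
                              csd_nm2=csd),
    )


class TestRankCandidates:
    def test_self_identical_candidate_scores_zero_and_ranks_first(self):
        ref = _make_reference()
        cands = [
            _candidate("itself", ref),
            _candidate("worse", ref, sym=1, cod=60.0, csa=40.0, csd=12.0,
                       img_noise=3.0),
        ]
        report = rank_candidates(ref, cands)
        assert report.best == "itself"
        row = report.table.set_index("label").loc["itself"]
        assert row["d_sum"] == pytest.approx(0.0, abs=1e-6)
        assert sorted(report.table["rank"]) == [1, 2]

    def test_monotone_in_single_discrepancy(self):
        ref = _make_reference()
        base = dict(sym=2, hnd=-1, csa=25.0, csd=0.0, img_noise=0.5)
        sums = []
        for cod in (47.7, 52.0, 60.0, 70.0):
            cands = [
                _candidate("probe", ref, cod=cod, **base, seed=2),
                _candidate("anchor", ref, cod=120.0, csa=60.0, csd=30.0,
                           img_noise=0.5, seed=2),
            ]
            report = rank_candidates(ref, cands)
            sums.append(report.table.set_index("label").loc["probe", "d_sum"])
        assert all(b >= a - 1e-9 for a, b in zip(sums, sums[1:]))

    def test_identical_candidates_tie_break_deterministic(self):
        ref = _make_reference()
        cands = [
            _candidate("b_map", ref, img_noise=0.5, seed=3),
            _candidate("a_map", ref, img_noise=0.5, seed=3),
            _candidate("anchor", ref, cod=90.0, csa=50.0, csd=20.0,
                       img_noise=2.0),
        ]
        r1 = rank_candidates(ref, cands)
        r2 = rank_candidates(ref, list(reversed(cands)))
        assert list(r1.table["label"]) == list(r2.table["label"])
        # equal scores: alphabetical label order breaks the tie
        assert list(r1.table["label"][:2]) == ["a_map", "b_map"]

    def test_order_invariance_of_scores(self):
        ref = _make_reference()
        cands = [
            _candidate("x", ref, cod=50.0, img_noise=1.0, seed=4),
            _candidate("y", ref, cod=55.0, csa=30.0, csd=5.0, img_noise=1.0,
                       seed=5),
            _candidate("z", ref, sym=1, cod=40.0, csa=20.0, csd=8.0,
                       img_noise=1.0, seed=6),
        ]
        t1 = rank_candidates(ref, cands).table.set_index("label")
        t2 = rank_candidates(ref, cands[::-1]).table.set_index("label")
        for label in "xyz":
            assert t1.loc[label, "d_sum"] == pytest.approx(
                t2.loc[label, "d_sum"], abs=1e-12
            )

    def test_bounds_hold_across_randomized_panels(self):
        rng = np.random.default_rng(9)
        ref = _make_reference()
        for trial in range(10):
            cands = [
                _candidate(
                    f"c{j}", ref,
                    sym=int(rng.integers(1, 4)),
                    hnd=int(rng.choice([-1, 1])),
                    cod=float(rng.uniform(30, 90)),
                    csa=float(rng.uniform(10, 60)),
                    csd=float(rng.uniform(0, 30)),
                    img_noise=float(rng.uniform(0.1, 3)),
                    seed=100 * trial + j,
                )
                for j in range(4)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NormalisationWarning)
                table = rank_candidates(ref, cands).table
            assert np.all((table["d_img"] >= -1e-12) & (table["d_img"] <= 2 + 1e-12))
            for par in ("d_sym", "d_hnd", "d_cod", "d_csa", "d_csd"):
                assert np.all((table[par] >= 0) & (table[par] <= 1 + 1e-12))
            assert np.all(table["d_sum"] <= 7 + 1e-9)
            assert sorted(table["rank"]) == list(range(1, 5))

    def test_fewer_than_two_candidates_rejected(self):
        ref = _make_reference()
        with pytest.raises(ValueError):
            rank_candidates(ref, [_candidate("only", ref)])
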