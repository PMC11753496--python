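import numpy as np
import pytest

from serpinkin.bfactor import (
    ResidueBMap,
    average_maps,
    diff_maps,
    minmax01,
    write_bfactor_column,
    znorm,
)
from serpinkin.errors import DegenerateInputError, InsufficientDataError
from serpinkin.io import read_structure_b
from serpinkin.simulate import make_toy_structures


def bmap(values, lineage="raw"):
    return ResidueBMap({("A", k, ""): v for k, v in values.items()}, lineage)


class TestZnorm:
    def test_three_residue_example(self):
        out = znorm(bmap({1: 10.0, 2: 20.0, 3: 30.0}))
        assert [out.values[("A", k, "")] for k in (1, 2, 3)] == [-1.0, 0.0, 1.0]
        assert out.lineage == "znorm"

    def test_idempotent_to_tolerance(self):
        once = znorm(bmap({1: 3.0, 2: 7.0, 3: 11.0, 4: 2.0}))
        twice = znorm(ResidueBMap(once.values, "raw"))
        for k in once.values:
            assert twice.values[k] == pytest.approx(once.values[k], abs=1e-12)

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(5)
        out = znorm(bmap({i: v for i, v in enumerate(20 + 5 * rng.standard_normal(50))}))
        vals = out.array()
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_map_rejected(self):
        with pytest.raises(DegenerateInputError):
            znorm(bmap({1: 5.0, 2: 5.0, 3: 5.0}))

    def test_too_few_residues(self):
        with pytest.raises(InsufficientDataError):
            znorm(bmap({1: 1.0, 2: 2.0}))


class TestAverageAndDiff:
    def test_average_of_opposites_is_zero(self):
        a = bmap({1: -1.0, 2: 1.0}, "znorm")
        b = bmap({1: 1.0, 2: -1.0}, "znorm")
        out = average_maps([a, b])
        assert all(v == 0.0 for v in out.values.values())

    def test_intersection_and_dropped_report(self):
        a = bmap({1: 1.0, 2: 2.0, 3: 3.0}, "znorm")
        b = bmap({2: 2.0, 3: 3.0, 4: 4.0}, "znorm")
        out = average_maps([a, b])
        assert sorted(k[1] for k in out.values) == [2, 3]
        assert sorted(k[1] for k in out.dropped) == [1, 4]

    def test_diff_with_self_is_zero(self):
        a = bmap({1: 0.3, 2: -0.8}, "znorm")
        assert all(v == 0.0 for v in diff_maps(a, a).values.values())

    def test_signed_antisymmetry_and_abs_consistency(self):
        a = bmap({1: 0.5, 2: -1.2, 3: 2.0}, "znorm")
        b = bmap({1: -0.5, 2: 0.3, 3: 2.5}, "znorm")
        fwd = diff_maps(a, b, "signed")
        rev = diff_maps(b, a, "signed")
        ab = diff_maps(a, b, "absolute")
        for k in fwd.values:
            assert fwd.values[k] == -rev.values[k]
            assert ab.values[k] == abs(fwd.values[k])

    def test_single_perturbed_residue_localised(self):
        base = {i: 0.0 for i in range(1, 10)}
        a = bmap(base | {5: 2.0}, "znorm")
        b = bmap(base, "znorm")
        out = diff_maps(a, b, "signed")
        assert out.values[("A", 5, "")] == 2.0
        assert all(v == 0.0 for k, v in out.values.items() if k[1] != 5)

    def test_lineage_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diff_maps(bmap({1: 1.0}, "znorm"), bmap({1: 1.0}, "raw"))


class TestMinMax:
    def test_basic_rescale(self):
        out = minmax01(bmap({1: 0.5, 2: 1.0, 3: 1.5}))
        assert [out.values[("A", k, "")] for k in (1, 2, 3)] == [0.0, 0.5, 1.0]

    def test_shift_invariant(self):
        a = minmax01(bmap({1: -3.0, 2: 0.0, 3: 1.0}))
        b = minmax01(bmap({1: 7.0, 2: 10.0, 3: 11.0}))
        assert a.values == b.values

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            minmax01(bmap({1: 1.0, 2: 1.0}))


class TestWriteColumn:
    def test_round_trip_and_formatting(self, tmp_path):
        path_a, _, _ = make_toy_structures(tmp_path, n_res=5, delta_b=0.0)
        values = {("A", i, ""): v for i, v in
                  zip(range(1, 6), [1.0, 123.456, 0.25, 7.5, 3.12])}
        out = tmp_path / "coloured.pdb"
        report = write_bfactor_column(path_a, ResidueBMap(values, "minmax01"), out)
        assert report["unmapped_residues"] == []
        text = out.read_text()
        assert "123.46" in text  # %6.2f formatting
        back = read_structure_b(out, "all_heavy")
        for k, v in values.items():
            assert back.values[k] == pytest.approx(v, abs=0.005)

    def test_unmapped_residues_zeroed_and_reported(self, tmp_path):
        path_a, _, _ = make_toy_structures(tmp_path, n_res=4, delta_b=0.0)
        out = tmp_path / "partial.pdb"
        report = write_bfactor_column(
            path_a, ResidueBMap({("A", 2, ""): 5.0}, "raw"), out)
        assert ("A", 1, "") in report["unmapped_residues"]
        back = read_structure_b(out)
        assert back.values[("A", 1, "")] == 0.0
        assert back.values[("A", 2, "")] == 5.0


def test_pipeline_recovers_injected_perturbation(tmp_path):
    """A region-localized B inflation is the argmax region of the rescaled
    absolute difference map."""
    region = (18, 24)
    path_a, path_b, truth = make_toy_structures(
        tmp_path, n_res=40, region=region, delta_b=10.0, seed=11)
    za = znorm(read_structure_b(path_a))
    zb = znorm(read_structure_b(path_b))
    final = minmax01(diff_maps(zb, za, "absolute"))
    n_region = region[1] - region[0] + 1
    top = sorted(final.values, key=final.values.get, reverse=True)[:n_region]
    assert sorted(k[1] for k in top) == list(range(region[0], region[1] + 1))
    assert max(final.values.values()) == 1.0
    assert min(final.values.values()) == 0.0


def test_identical_pair_gives_zero_difference(tmp_path):
    path_a, path_b, _ = make_toy_structures(tmp_path, n_res=10, delta_b=0.0)
    da = diff_maps(read_structure_b(path_a), read_structure_b(path_b), "absolute")
    assert all(v == 0.0 for v in da.values.values())
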