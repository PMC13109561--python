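"""Mixed-augmentation algebra, pair enumeration, and end-to-end runs.

The enumeration tests compare against an independent brute-force oracle that
checks every ordered pair of records in a group against the three eligibility
predicates (same-view adjacent dates; front/side same date; front-at-t with
side-at-the-next-date).
"""

import hashlib
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from i2v import (
    DatasetManifest,
    ImageRecord,
    MixJob,
    MixReport,
    enumerate_mix_jobs,
    mixgen,
    run_gmma,
    split_dataset,
)
from i2v.dataset import date_sort_key


# --------------------------------------------------------------------- #
# mixgen algebra
# --------------------------------------------------------------------- #
class TestMixgen:
    def test_midpoint_value(self):
        a = np.full((2, 2, 3), 100, dtype=np.uint8)
        b = np.full((2, 2, 3), 200, dtype=np.uint8)
        assert np.all(mixgen(a, b, 0.5) == 150)

    def test_lambda_one_is_identity(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 256, (5, 7, 3), dtype=np.uint8)
        b = rng.integers(0, 256, (5, 7, 3), dtype=np.uint8)
        assert np.array_equal(mixgen(a, b, 1.0), a)
        assert np.array_equal(mixgen(a, b, 0.0), b)

    def test_fixed_point_on_identical_inputs(self):
        a = np.random.default_rng(1).integers(0, 256, (4, 4, 3), dtype=np.uint8)
        assert np.array_equal(mixgen(a, a, 0.5), a)

    def test_dimension_mismatch_message(self):
        with pytest.raises(ValueError, match="preprocess"):
            mixgen(np.zeros((2, 2, 3), np.uint8), np.zeros((3, 2, 3), np.uint8), 0.5)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 1.0))
    def test_bounds_and_symmetry(self, seed, lam):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 256, (6, 5, 3), dtype=np.uint8)
        b = rng.integers(0, 256, (6, 5, 3), dtype=np.uint8)
        mixed = mixgen(a, b, lam).astype(int)
        lo = np.minimum(a, b).astype(int)
        hi = np.maximum(a, b).astype(int)
        assert np.all(mixed >= lo) and np.all(mixed <= hi)
        if lam == 0.5:
            other = mixgen(b, a, 0.5).astype(int)
            assert np.abs(mixed - other).max() <= 1


# --------------------------------------------------------------------- #
# enumeration vs brute force
# --------------------------------------------------------------------- #
def brute_force_jobs(group):
    """Test every ordered pair against the three eligibility predicates."""
    raw = [r for r in group if not r.is_mixed]
    if len(raw) <= 1:
        return Counter()
    acc_dates = sorted({r.date for r in raw}, key=date_sort_key)

    def successor(dates, d):
        i = dates.index(d)
        return dates[i + 1] if i + 1 < len(dates) else None

    jobs = Counter()
    for a in raw:
        for b in raw:
            if a is b or a.accession != b.accession:
                continue
            view_dates = sorted({r.date for r in raw if r.viewpoint == a.viewpoint},
                                key=date_sort_key)
            if (a.viewpoint == b.viewpoint
                    and successor(view_dates, a.date) == b.date):
                jobs[("temporal", a.path, b.path)] += 1
            if (a.date == b.date and a.viewpoint == "front"
                    and b.viewpoint == "side"):
                jobs[("viewpoint", a.path, b.path)] += 1
            if (a.viewpoint == "front" and b.viewpoint == "side"
                    and successor(acc_dates, a.date) == b.date):
                jobs[("view_stage", a.path, b.path)] += 1
    return jobs


def _rec(acc, date, view, tag="p"):
    return ImageRecord(path=f"{acc}_{tag}_{date}_{view}", accession=acc,
                       tag=tag, date=str(date), viewpoint=view)


def full_grid_group(acc, n_dates):
    return [_rec(acc, 10 + d, v) for d in range(n_dates)
            for v in ("front", "side")]


class TestEnumerateMixJobs:
    def test_two_date_group_has_five_jobs(self):
        jobs = enumerate_mix_jobs(full_grid_group("A", 2))
        counts = Counter(j.mix_type for j in jobs)
        assert counts == {"viewpoint": 2, "temporal": 2, "view_stage": 1}

    def test_singleton_group_yields_nothing(self):
        assert enumerate_mix_jobs([_rec("A", 1, "front")]) == []

    @pytest.mark.parametrize("n_dates", range(1, 7))
    def test_closed_form_on_full_grid(self, n_dates):
        jobs = enumerate_mix_jobs(full_grid_group("A", n_dates))
        counts = Counter(j.mix_type for j in jobs)
        assert counts["viewpoint"] == n_dates
        assert counts["temporal"] == 2 * (n_dates - 1)
        assert counts["view_stage"] == n_dates - 1
        assert len(jobs) == 4 * n_dates - 3
        assert brute_force_jobs(full_grid_group("A", n_dates)) == Counter(
            {(j.mix_type, j.left.path, j.right.path): 1 for j in jobs})

    def test_front_only_group_has_only_temporal(self):
        group = [_rec("A", d, "front") for d in range(4)]
        counts = Counter(j.mix_type for j in enumerate_mix_jobs(group))
        assert counts == {"temporal": 3}

    def test_irregular_dates_use_immediate_successor(self):
        group = [_rec("A", d, "front") for d in (1, 5, 50)]
        jobs = enumerate_mix_jobs(group)
        pairs = {(j.left.date, j.right.date) for j in jobs}
        assert pairs == {("1", "5"), ("5", "50")}

    def test_multiple_images_per_slot_cartesian(self):
        group = [_rec("A", 1, "front", f"a{i}") for i in range(2)] + \
                [_rec("A", 1, "side", f"b{i}") for i in range(3)]
        jobs = enumerate_mix_jobs(group)
        assert Counter(j.mix_type for j in jobs) == {"viewpoint": 6}

    def test_symmetric_view_stage_option(self):
        group = full_grid_group("A", 3)
        base = Counter(j.mix_type for j in enumerate_mix_jobs(group))
        sym = Counter(j.mix_type for j in
                      enumerate_mix_jobs(group, view_stage_symmetric=True))
        assert sym["view_stage"] == 2 * base["view_stage"]

    def test_mixed_accessions_rejected(self):
        with pytest.raises(ValueError):
            enumerate_mix_jobs([_rec("A", 1, "front"), _rec("B", 1, "side")])

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_on_random_manifests(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        dates = [str(d) for d in sorted(rng.choice(60, size=6, replace=False))]
        group = []
        for i in range(n):
            group.append(_rec("A", rng.choice(dates),
                              rng.choice(["front", "side"]), tag=f"t{i}"))
        jobs = enumerate_mix_jobs(group)
        got = Counter({(j.mix_type, j.left.path, j.right.path): 1 for j in jobs})
        assert sum(got.values()) == len(jobs)  # no duplicate jobs
        assert got == brute_force_jobs(group)

    def test_label_consistency_and_ordering(self):
        group = full_grid_group("A", 4)
        jobs = enumerate_mix_jobs(group)
        assert all(j.left.accession == j.right.accession == "A" for j in jobs)
        keys = [(j.mix_type, j.left.sort_key, j.right.sort_key) for j in jobs]
        assert keys == sorted(keys)


class TestMixJobInvariants:
    def test_cross_accession_rejected(self):
        with pytest.raises(ValueError):
            MixJob(_rec("A", 1, "front"), _rec("B", 1, "side"), "viewpoint")

    def test_report_total_identity(self):
        r = MixReport(n_original=10, n_viewpoint=3, n_temporal=4, n_view_stage=2)
        assert r.n_total == 19 and r.n_mixed == 9


# --------------------------------------------------------------------- #
# run_gmma end to end
# --------------------------------------------------------------------- #
class TestRunGmma:
    def test_counts_files_and_records_agree(self, tmp_path, small_dataset):
        manifest, _ = small_dataset
        split = split_dataset(manifest, 0.25, seed=3)
        out = tmp_path / "mixed"
        augmented, report = run_gmma(split, out, lam=0.5)
        n_files = len(list(out.glob("*.png")))
        n_new = len(augmented.records) - len(split.records)
        assert report.n_total == report.n_original + report.n_mixed
        assert report.n_original == len(split.records)
        assert n_files == report.n_mixed == n_new
        assert report.n_total == len(augmented.records)

    def test_full_grid_counts(self, tmp_path, small_dataset):
        manifest, config = small_dataset
        full = manifest.clone()
        for r in full.records:
            r.split = "train"
        _, report = run_gmma(full, tmp_path / "m")
        d, a = config.n_dates, config.n_accessions
        assert report.n_viewpoint == a * d
        assert report.n_temporal == a * 2 * (d - 1)
        assert report.n_view_stage == a * (d - 1)

    def test_mixed_records_are_train_only_same_accession(self, tmp_path,
                                                         small_dataset):
        manifest, _ = small_dataset
        split = split_dataset(manifest, 0.25, seed=3)
        augmented, _ = run_gmma(split, tmp_path / "m")
        mixed = [r for r in augmented.records if r.is_mixed]
        assert mixed and all(r.split == "train" for r in mixed)
        test_paths = {r.path for r in split.records if r.split == "test"}
        assert all(r.path not in test_paths for r in mixed)

    def test_empty_train_split(self, tmp_path, small_dataset):
        manifest, _ = small_dataset
        empty = manifest.clone()
        for r in empty.records:
            r.split = "test"
        augmented, report = run_gmma(empty, tmp_path / "m")
        assert report.n_mixed == 0
        assert not list((tmp_path / "m").glob("*.png"))
        assert len(augmented.records) == len(empty.records)

    def test_byte_identical_reruns(self, tmp_path, small_dataset):
        manifest, _ = small_dataset
        split = split_dataset(manifest, 0.25, seed=3)
        digests = []
        for sub in ("m1", "m2"):
            out = tmp_path / sub
            run_gmma(split, out)
            digests.append(sorted(
                (p.name, hashlib.sha256(p.read_bytes()).hexdigest())
                for p in out.glob("*.png")))
        assert digests[0] == digests[1]

    def test_mixed_pixels_within_parent_bounds(self, tmp_path, small_dataset):
        from i2v.dataset import load_image

        manifest, _ = small_dataset
        full = manifest.clone()
        for r in full.records:
            r.split = "train"
        augmented, _ = run_gmma(full, tmp_path / "m")
        by_key = {}
        for r in full.records:
            by_key[(r.accession, r.date, r.viewpoint)] = r
        checked = 0
        for r in augmented.records:
            if not r.is_mixed or not r.tag.endswith("viewpoint"):
                continue
            left = load_image(by_key[(r.accession, r.date, "front")].path)
            right = load_image(by_key[(r.accession, r.date, "side")].path)
            mixed = load_image(r.path).astype(int)
            assert np.all(mixed >= np.minimum(left, right))
            assert np.all(mixed <= np.maximum(left, right))
            checked += 1
        assert checked > 0
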