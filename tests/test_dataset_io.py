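"""Dataset layout scanning, prevalence, resizing, splitting, balancing."""

import shutil

import numpy as np
import pandas as pd
import pytest

from dermoseg.dataset_io import (
    ATTRIBUTES,
    DatasetManifest,
    SplitSpec,
    balance_downsample,
    load_mask,
    resize_pair,
    scan_isic_layout,
    split_dataset,
    summarize_prevalence,
    write_mask,
)


def _fake_manifest(n, pos_flags):
    """Synthetic manifest table: pos_flags maps attribute -> bool array."""
    rows = []
    for i in range(n):
        row = {"image_id": f"img{i:03d}", "image_path": f"img{i:03d}.jpg"}
        for a in ATTRIBUTES:
            row[f"mask_{a}"] = f"img{i:03d}_attribute_{a}.png"
            flags = pos_flags.get(a)
            row[f"pos_{a}"] = int(100 * bool(flags[i])) if flags is not None else 0
        rows.append(row)
    return DatasetManifest(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# scanning


def test_scan_counts_and_pairings(tiny_dataset):
    manifest = scan_isic_layout(tiny_dataset["dir"])
    assert len(manifest) == 10
    mask_cols = [c for c in manifest.df.columns if c.startswith("mask_")]
    assert len(mask_cols) == 5
    assert manifest.df[mask_cols].notna().all().all()  # 50 mask paths resolved


def test_scan_matches_generator_ledger(tiny_dataset):
    manifest = scan_isic_layout(tiny_dataset["dir"])
    ledger = tiny_dataset["ledger"].set_index("image_id")
    for _, row in manifest.df.iterrows():
        for a in ATTRIBUTES:
            assert row[f"pos_{a}"] == ledger.loc[row["image_id"], f"painted_{a}"]


def test_scan_missing_mask_is_explicit_error(tiny_dataset, tmp_path):
    broken = tmp_path / "broken"
    shutil.copytree(tiny_dataset["dir"], broken)
    victim = next(broken.glob("*_attribute_globules.png"))
    victim.unlink()
    with pytest.raises(FileNotFoundError, match="globules"):
        scan_isic_layout(broken)


def test_blank_mask_counts_as_negative(tmp_path):
    from PIL import Image

    img_id = "ISIC_0000001"
    Image.new("RGB", (64, 64)).save(tmp_path / f"{img_id}.jpg")
    for a in ATTRIBUTES:
        write_mask(tmp_path / f"{img_id}_attribute_{a}.png", np.zeros((64, 64), dtype=np.uint8))
    manifest = scan_isic_layout(tmp_path)
    assert all(manifest.df[f"pos_{a}"].iloc[0] == 0 for a in ATTRIBUTES)
    assert manifest.attribute_counts() == {a: 0 for a in ATTRIBUTES}


# ---------------------------------------------------------------------------
# prevalence


def test_prevalence_percent_arithmetic():
    flags = {"pigment_network": [1, 1, 1, 0, 0, 0], "globules": [1, 0, 0, 0, 0, 0]}
    manifest = _fake_manifest(6, flags)
    table = summarize_prevalence(manifest).set_index("attribute")
    assert table.loc["pigment_network", "count"] == 3
    assert table.loc["pigment_network", "percent"] == 50.0
    assert table.loc["globules", "percent"] == pytest.approx(16.7)
    assert table.loc["streaks", "percent"] == 0.0


def test_prevalence_of_isic_task2_composition():
    """Published counts of the ISIC 2018 Task 2 set: 1522/189/681 of 2594."""
    for count, expected in [(1522, 58.7), (189, 7.3), (681, 26.3), (602, 23.2)]:
        assert round(100.0 * count / 2594, 1) == expected


# ---------------------------------------------------------------------------
# resizing


def test_resize_pair_keeps_mask_binary(rng):
    img = rng.random((60, 45, 3)).astype(np.float32)
    mask = (rng.random((60, 45)) < 0.2).astype(np.uint8)
    img2, mask2 = resize_pair(img, mask, 64)
    assert img2.shape == (64, 64, 3) and mask2.shape == (64, 64)
    assert set(np.unique(mask2)) <= {0, 1}


def test_resize_identity_is_bit_identical(rng):
    img = rng.random((64, 64, 3)).astype(np.float32)
    mask = (rng.random((64, 64)) < 0.2).astype(np.uint8)
    img2, mask2 = resize_pair(img, mask, 64)
    np.testing.assert_array_equal(mask2, mask)
    np.testing.assert_array_equal(img2, img)


def test_halfplane_downsize_preserves_foreground_fraction():
    side = 128
    mask = np.zeros((side, side), dtype=np.uint8)
    mask[:, : side // 2] = 1
    img = np.zeros((side, side, 3), dtype=np.float32)
    _, small = resize_pair(img, mask, 64)
    assert abs(small.mean() - 0.5) <= 2 / 64


def test_resize_requires_multiple_of_32(rng):
    with pytest.raises(ValueError):
        resize_pair(rng.random((64, 64, 3)), np.zeros((64, 64), dtype=np.uint8), 60)


def test_mask_write_read_roundtrip(tmp_path, rng):
    mask = (rng.random((33, 47)) < 0.3).astype(np.uint8)
    path = tmp_path / "m.png"
    write_mask(path, mask)
    np.testing.assert_array_equal(load_mask(path), mask)


# ---------------------------------------------------------------------------
# splitting


def test_split_sizes_and_disjointness():
    manifest = _fake_manifest(100, {"globules": [i % 3 == 0 for i in range(100)]})
    train, val, test = split_dataset(manifest, SplitSpec(seed=3))
    assert len(train) + len(val) + len(test) == 100
    assert len(train) + len(val) == 80  # floor(0.8 * 100)
    assert len(val) == 8  # floor(0.1 * 80)
    ids = [set(m.image_ids) for m in (train, val, test)]
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])


def test_split_floor_rule_small_n():
    manifest = _fake_manifest(10, {})
    train, val, test = split_dataset(manifest, SplitSpec(seed=0))
    assert len(test) == 2 and len(train) + len(val) == 8


def test_split_determinism():
    manifest = _fake_manifest(40, {"streaks": [i % 5 == 0 for i in range(40)]})
    a = split_dataset(manifest, SplitSpec(seed=11))
    b = split_dataset(manifest, SplitSpec(seed=11))
    for ma, mb in zip(a, b):
        assert ma.image_ids == mb.image_ids
    c = split_dataset(manifest, SplitSpec(seed=12))
    assert any(ma.image_ids != mc.image_ids for ma, mc in zip(a, c))


def test_split_stratifies_positivity():
    flags = {"globules": [i < 50 for i in range(100)]}
    manifest = _fake_manifest(100, flags)
    _, _, test = split_dataset(manifest, SplitSpec(seed=1))
    pos_in_test = int((test.df["pos_globules"] > 0).sum())
    assert pos_in_test == 10  # exactly proportional: 20% of the 50 positives


def test_split_rejects_tiny_manifest():
    with pytest.raises(ValueError):
        split_dataset(_fake_manifest(4, {}), SplitSpec())


# ---------------------------------------------------------------------------
# balancing


def test_balance_downsample_rule():
    flags = {"streaks": [i < 10 for i in range(60)]}
    manifest = _fake_manifest(60, flags)
    balanced = balance_downsample(manifest, "streaks", seed=4)
    pos = (balanced.df["pos_streaks"] > 0).sum()
    neg = (balanced.df["pos_streaks"] == 0).sum()
    assert pos == 10 and neg == 10
    assert not balanced.df["image_id"].duplicated().any()
    # every positive retained
    orig_pos = set(manifest.positives("streaks")["image_id"])
    assert orig_pos <= set(balanced.image_ids)


def test_balance_keeps_all_when_positives_dominate():
    flags = {"globules": [True] * 20}
    manifest = _fake_manifest(20, flags)
    balanced = balance_downsample(manifest, "globules", seed=0)
    assert balanced.image_ids == manifest.image_ids


def test_balance_determinism_and_errors():
    flags = {"milia_like_cyst": [i % 4 == 0 for i in range(40)]}
    manifest = _fake_manifest(40, flags)
    a = balance_downsample(manifest, "milia_like_cyst", seed=9)
    b = balance_downsample(manifest, "milia_like_cyst", seed=9)
    assert a.image_ids == b.image_ids
    with pytest.raises(ValueError, match="streaks"):
        balance_downsample(manifest, "streaks", seed=0)
    with pytest.raises(ValueError):
        balance_downsample(manifest, "not_an_attribute", seed=0)


# ---------------------------------------------------------------------------
# manifest round-trip


def test_manifest_csv_roundtrip(tmp_path, tiny_dataset):
    manifest = scan_isic_layout(tiny_dataset["dir"])
    path = tmp_path / "manifest.csv"
    manifest.to_csv(path)
    again = DatasetManifest.from_csv(path)
    pd.testing.assert_frame_equal(manifest.df, again.df)


def test_rescan_is_identical(tiny_dataset):
    a = scan_isic_layout(tiny_dataset["dir"])
    b = scan_isic_layout(tiny_dataset["dir"])
    assert a == b
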