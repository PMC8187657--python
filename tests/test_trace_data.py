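"""Trace ingestion, imputation, distance matrices, standardization, splits."""

import io
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracenet.trace_data import (
    DistanceMatrix,
    NormStats,
    PolymerTrace,
    TraceError,
    apply_normalizer,
    build_dataset,
    fit_normalizer,
    interpolate_missing,
    invert_normalizer,
    read_trace_table,
    stratified_split,
    trace_to_distance_matrix,
    traces_to_matrices,
    write_trace_table,
)

B = 52


def make_trace(coords, cell_id="c1"):
    return PolymerTrace(cell_id=cell_id, coords=np.asarray(coords, dtype=float))


def full_trace(rng, cell_id="c1"):
    return make_trace(rng.normal(scale=100, size=(B, 3)), cell_id)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _csv(text):
    return io.StringIO(textwrap.dedent(text))


def _complete_cell_rows(cell, rng, skip=(), nan_barcode=None):
    rows = []
    for b in range(1, B + 1):
        if b in skip:
            continue
        x, y, z = rng.normal(scale=100, size=3)
        if b == nan_barcode:
            z = "nan"
        rows.append(f"{cell},{b},{x:.2f},{y:.2f},{z}")
    return rows


def test_read_trace_table_complete_and_missing_and_reject(rng, tmp_path):
    rows = ["cell_id,barcode,x,y,z,gene_on"]
    # two complete cells, one with a NaN z, one with a single observed barcode
    for cell in ("a", "b"):
        rows += [r + ",1" for r in _complete_cell_rows(cell, rng)]
    rows += [r + ",0" for r in _complete_cell_rows("c", rng, nan_barcode=10)]
    rows += [f"d,1,0.0,0.0,0.0,0"]
    path = tmp_path / "traces.csv"
    path.write_text("\n".join(rows))

    traces, labels, qc = read_trace_table(
        path, label_columns=["gene_on"]
    )
    assert qc.n_cells == 3 and qc.n_rejected == 1 and qc.rejected_ids == ["d"]
    by_id = {t.cell_id: t for t in traces}
    assert by_id["a"].is_complete and by_id["b"].is_complete
    assert not by_id["c"].observed_mask[9]  # NaN z -> barcode 10 missing
    assert by_id["c"].n_observed == B - 1
    assert labels.loc["a", "gene_on"] == 1 and labels.loc["c", "gene_on"] == 0


def test_read_trace_table_malformed_barcode_reports_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("cell_id,barcode,x,y,z\na,1,0,0,0\na,999,1,1,1\n")
    with pytest.raises(TraceError, match="line 3"):
        read_trace_table(path)


def test_trace_table_round_trip(rng, tmp_path):
    traces = [full_trace(rng, f"t{i}") for i in range(3)]
    traces[1].coords[5] = np.nan
    path = tmp_path / "rt.csv"
    write_trace_table(traces, path)
    back, _, qc = read_trace_table(path)
    assert qc.n_rejected == 0
    assert not back[1].observed_mask[5]
    np.testing.assert_allclose(back[0].coords, traces[0].coords, atol=1e-6)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def test_interpolate_midpoint(rng):
    t = full_trace(rng)
    t.coords[10] = (0.0, 0.0, 0.0)
    t.coords[12] = (2.0, 2.0, 2.0)
    t.coords[11] = np.nan
    out = interpolate_missing(t)
    np.testing.assert_allclose(out.coords[11], (1.0, 1.0, 1.0))


def test_interpolate_two_missing_thirds(rng):
    t = full_trace(rng)
    t.coords[20] = (0.0, 0.0, 0.0)
    t.coords[23] = (3.0, 0.0, 0.0)
    t.coords[21] = np.nan
    t.coords[22] = np.nan
    out = interpolate_missing(t)
    np.testing.assert_allclose(out.coords[21], (1.0, 0.0, 0.0), atol=1e-12)
    np.testing.assert_allclose(out.coords[22], (2.0, 0.0, 0.0), atol=1e-12)


def test_interpolate_end_fill_copies_nearest(rng):
    t = full_trace(rng)
    t.coords[0] = np.nan
    t.coords[1] = (5.0, 5.0, 5.0)
    out = interpolate_missing(t)
    np.testing.assert_allclose(out.coords[0], (5.0, 5.0, 5.0))
    with pytest.raises(TraceError):
        interpolate_missing(t, end_policy="reject")


def test_interpolate_rejects_underobserved():
    coords = np.full((B, 3), np.nan)
    coords[0] = coords[1] = 0.0
    t = make_trace(coords)
    t.coords[1] = np.nan  # now only one observed
    with pytest.raises(TraceError):
        interpolate_missing(t)


@settings(deadline=None, max_examples=20)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_interpolation_idempotent_on_complete(seed):
    t = full_trace(np.random.default_rng(seed))
    out = interpolate_missing(t)
    np.testing.assert_array_equal(out.coords, t.coords)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_3_4_5():
    coords = np.zeros((B, 3))
    coords[:, 0] = np.arange(B) * 10.0  # spread out to keep points distinct
    coords[1] = (3.0, 4.0, 0.0)
    m = trace_to_distance_matrix(make_trace(coords))
    assert m.values[0, 1] == pytest.approx(5.0)


def test_distance_matrix_matches_double_loop(rng):
    t = full_trace(rng)
    m = trace_to_distance_matrix(t).values
    brute = np.zeros((B, B))
    for i in range(B):
        for j in range(B):
            brute[i, j] = np.sqrt(((t.coords[i] - t.coords[j]) ** 2).sum())
    np.testing.assert_allclose(m, brute, atol=1e-9)
    np.testing.assert_array_equal(m, m.T)
    np.testing.assert_array_equal(np.diag(m), np.zeros(B))


def test_distance_triangle_inequality(rng):
    m = trace_to_distance_matrix(full_trace(rng)).values
    # d(i,k) <= d(i,j) + d(j,k) entrywise over all triples
    lhs = m[:, None, :]
    rhs = m[:, :, None] + m[None, :, :]
    assert (lhs <= rhs + 1e-9).all()


def test_distance_requires_complete_trace(rng):
    t = full_trace(rng)
    t.coords[7] = np.nan
    with pytest.raises(TraceError, match="interpolate"):
        trace_to_distance_matrix(t)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_fit_normalizer_degenerate_and_oracle(rng):
    m = trace_to_distance_matrix(full_trace(rng)).values
    stats = fit_normalizer(np.stack([m, m]))
    np.testing.assert_allclose(stats.mean, m)
    assert (stats.std == stats.epsilon).all()

    batch = np.stack([trace_to_distance_matrix(full_trace(rng)).values for _ in range(7)])
    stats = fit_normalizer(batch)
    # independent two-pass mean/variance
    mu = sum(batch) / 7
    var = sum((b - mu) ** 2 for b in batch) / 7
    np.testing.assert_allclose(stats.mean, mu, atol=1e-9)
    np.testing.assert_allclose(stats.std, np.maximum(np.sqrt(var), 1e-6), atol=1e-9)


def test_self_standardization_is_zero_mean_unit_std(ensemble_distances):
    batch = ensemble_distances[:200]
    stats = fit_normalizer(batch)
    z = np.stack([apply_normalizer(b, stats).values for b in batch])
    off = ~np.eye(52, dtype=bool)
    assert np.abs(z.mean(axis=0)[off]).max() < 1e-9
    assert np.abs(z.std(axis=0)[off] - 1.0).max() < 1e-6


def test_apply_normalizer_anchors(rng):
    batch = np.stack(
        [trace_to_distance_matrix(full_trace(rng)).values for _ in range(5)]
    )
    stats = fit_normalizer(batch)
    zero = apply_normalizer(stats.mean, stats).values
    np.testing.assert_allclose(zero, 0.0, atol=1e-9)
    ones = apply_normalizer(stats.mean + stats.std, stats).values
    np.testing.assert_allclose(ones, 1.0, atol=1e-9)


def test_normalizer_round_trip(rng):
    batch = np.stack(
        [trace_to_distance_matrix(full_trace(rng)).values for _ in range(5)]
    )
    stats = fit_normalizer(batch)
    z = apply_normalizer(batch[0], stats)
    back = invert_normalizer(z, stats)
    np.testing.assert_allclose(back.values, batch[0], atol=1e-8)


def test_mean_ratio_mode(rng):
    batch = np.abs(
        np.stack([trace_to_distance_matrix(full_trace(rng)).values for _ in range(5)])
    )
    stats = fit_normalizer(batch, mode="mean_ratio")
    z = apply_normalizer(batch[0], stats).values
    off = ~np.eye(B, dtype=bool)
    np.testing.assert_allclose(
        z[off], batch[0][off] / stats.mean[off], atol=1e-9
    )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_split_sizes_and_determinism():
    labels = (np.arange(1000) < 400).astype(int)  # 40% ON
    codes = stratified_split(labels, (0.6, 0.2, 0.2), seed=3)
    counts = np.bincount(codes)
    assert list(counts) == [600, 200, 200]
    codes2 = stratified_split(labels, (0.6, 0.2, 0.2), seed=3)
    np.testing.assert_array_equal(codes, codes2)
    for code in range(3):
        frac = labels[codes == code].mean()
        assert 0.38 <= frac <= 0.42


def test_split_fractions_must_sum_to_one():
    with pytest.raises(TraceError):
        stratified_split(np.array([0, 1] * 10), (0.5, 0.2, 0.2))


def test_build_dataset_norm_stats_from_train_only(ensemble_distances):
    labels = (np.arange(len(ensemble_distances)) % 3 == 0).astype(int)
    ds = build_dataset(ensemble_distances, labels, seed=4)
    stats = fit_normalizer(ds.matrices[ds.indices("train")])
    np.testing.assert_allclose(ds.norm_stats.mean, stats.mean)
    np.testing.assert_allclose(ds.norm_stats.std, stats.std)


def test_hdf5_round_trip(tmp_path, ensemble_distances):
    labels = (np.arange(len(ensemble_distances)) % 2).astype(int)
    ds = build_dataset(ensemble_distances[:100], labels[:100], seed=5)
    path = tmp_path / "ds.h5"
    ds.to_hdf5(path)
    from tracenet.trace_data import LabeledDataset

    back = LabeledDataset.from_hdf5(path)
    np.testing.assert_array_equal(back.labels, ds.labels)
    np.testing.assert_array_equal(back.split, ds.split)
    np.testing.assert_allclose(back.matrices, ds.matrices)
    np.testing.assert_allclose(back.norm_stats.mean, ds.norm_stats.mean)
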