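"""Container validation and delimited-table round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oxbscreen as ox
from oxbscreen.panel import ROLES


def _write_tables(tmp_path, frames, sep="\t", suffix=".tsv"):
    paths = {}
    for role, frame in frames.items():
        path = tmp_path / f"{role}{suffix}"
        frame.to_csv(path, sep=sep)
        paths[role] = path
    return paths


def _toy_frames(values=None):
    idx = ["cg01", "cg02"]
    cols = ["s1", "s2"]
    frames = {}
    for k, role in enumerate(ROLES):
        base = np.arange(4, dtype=float).reshape(2, 2) + 10 * (k + 1)
        frames[role] = pd.DataFrame(values if values is not None else base,
                                    index=idx, columns=cols)
    return frames


class TestReadPanel:
    def test_identity_round_trip(self, tmp_path):
        frames = _toy_frames()
        panel = ox.read_panel(_write_tables(tmp_path, frames), tissue="healthy")
        assert panel.shape == (2, 2)
        assert panel.mask.all()
        assert panel.tissue == "healthy"
        for role in ROLES:
            np.testing.assert_array_equal(panel.frame(role).to_numpy(),
                                          frames[role].to_numpy())

    def test_csv_autodetected(self, tmp_path):
        frames = _toy_frames()
        paths = _write_tables(tmp_path, frames, sep=",", suffix=".csv")
        panel = ox.read_panel(paths)
        assert panel.shape == (2, 2) and panel.mask.all()

    def test_missing_sample_raises_alignment_error(self, tmp_path):
        frames = _toy_frames()
        frames["U_oxbs"] = frames["U_oxbs"].drop(columns=["s2"])
        with pytest.raises(ox.AlignmentError, match="U_oxbs"):
            ox.read_panel(_write_tables(tmp_path, frames))

    def test_missing_file_names_role(self, tmp_path):
        frames = _toy_frames()
        paths = _write_tables(tmp_path, frames)
        del paths["M_oxbs"]
        with pytest.raises(ox.PanelError, match="M_oxbs"):
            ox.read_panel(paths)

    def test_negative_cell_masked_and_counted(self, tmp_path, caplog):
        frames = _toy_frames()
        frames["U_oxbs"].iloc[0, 1] = -5.0
        with caplog.at_level("WARNING", logger="oxbscreen"):
            panel = ox.read_panel(_write_tables(tmp_path, frames))
        assert not panel.mask[0, 1]
        assert panel.mask.sum() == 3
        assert "masked 1 invalid cell" in caplog.text

    def test_non_numeric_cell_masked(self, tmp_path):
        frames = _toy_frames()
        frames["M_bs"] = frames["M_bs"].astype(object)
        frames["M_bs"].iloc[1, 0] = "oops"
        panel = ox.read_panel(_write_tables(tmp_path, frames))
        assert not panel.mask[1, 0] and panel.mask.sum() == 3

    def test_na_tokens_accepted_as_missing(self, tmp_path):
        frames = _toy_frames()
        frames["M_bs"] = frames["M_bs"].astype(object)
        frames["M_bs"].iloc[0, 0] = "NA"
        frames["U_bs"] = frames["U_bs"].astype(object)
        frames["U_bs"].iloc[0, 1] = "NaN"
        panel = ox.read_panel(_write_tables(tmp_path, frames))
        assert not panel.mask[0, 0] and not panel.mask[0, 1]

    def test_reordered_columns_are_aligned_not_dropped(self, tmp_path):
        frames = _toy_frames()
        frames["U_bs"] = frames["U_bs"][["s2", "s1"]]
        frames["M_oxbs"] = frames["M_oxbs"].loc[["cg02", "cg01"]]
        panel = ox.read_panel(_write_tables(tmp_path, frames))
        assert panel.n_probes == 2
        # values must land on the canonical probe/sample grid
        assert panel.frame("U_bs").loc["cg01", "s1"] == 20.0


class TestContainers:
    def test_duplicate_probe_ids_rejected(self):
        with pytest.raises(ox.PanelError, match="duplicate"):
            ox.IntensityPanel(["p1", "p1"], ["s1"], [[1.0], [2.0]], [[1.0], [2.0]],
                              [[1.0], [2.0]], [[1.0], [2.0]])

    def test_unmasked_negative_intensity_rejected(self):
        with pytest.raises(ox.PanelError, match="finite"):
            ox.IntensityPanel(["p1"], ["s1"], [[-1.0]], [[1.0]], [[1.0]], [[1.0]])

    def test_masked_entries_may_be_anything(self):
        panel = ox.IntensityPanel(["p1"], ["s1"], [[np.nan]], [[1.0]], [[1.0]], [[1.0]],
                                  mask=np.array([[False]]))
        assert not panel.mask.any()

    def test_alpha_presence_enforced(self):
        ok = dict(values=[[0.5]], mask=[[True]], probe_ids=["p"], sample_ids=["s"])
        with pytest.raises(ox.PanelError, match="alpha"):
            ox.MeasureMatrix("delta_beta", **ok)  # missing alpha
        with pytest.raises(ox.PanelError, match="alpha"):
            ox.MeasureMatrix("delta_h", alpha=100.0, **ok)  # spurious alpha

    def test_delta_beta_bounds_enforced(self):
        with pytest.raises(ox.PanelError, match=r"\[-1, 1\]"):
            ox.MeasureMatrix("delta_beta", values=[[1.5]], mask=[[True]],
                             probe_ids=["p"], sample_ids=["s"], alpha=100.0)


class TestWriteTable:
    def test_measure_matrix_single_na(self, tmp_path):
        m = ox.MeasureMatrix("delta_h", values=[[0.25, np.nan]], mask=[[True, False]],
                             probe_ids=["p"], sample_ids=["s1", "s2"])
        path = tmp_path / "m.tsv"
        ox.write_table(m, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert "".join(body).count("NA") == 1

    def test_measure_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        values = rng.uniform(-1, 1, (5, 3))
        mask = rng.random((5, 3)) > 0.2
        m = ox.MeasureMatrix("delta_beta", values=np.where(mask, values, np.nan),
                             mask=mask, probe_ids=[f"p{i}" for i in range(5)],
                             sample_ids=["a", "b", "c"], alpha=100.0)
        path = tmp_path / "m.tsv"
        ox.write_table(m, path)
        back = ox.read_measure_matrix(path)
        assert back.measure_name == "delta_beta" and back.alpha == 100.0
        np.testing.assert_array_equal(back.mask, mask)
        np.testing.assert_allclose(back.values[mask], values[mask], rtol=1e-12)

    def test_call_round_trip(self, tmp_path):
        calls = ox.CallMatrix("delta_h", calls=[[True, False]], mask=[[True, False]],
                              probe_ids=["p"], sample_ids=["s1", "s2"], threshold=0.3)
        path = tmp_path / "c.tsv"
        ox.write_table(calls, path)
        back = ox.read_call_matrix(path)
        assert back.threshold == 0.3
        np.testing.assert_array_equal(back.calls & back.mask, calls.calls & calls.mask)
        np.testing.assert_array_equal(back.mask, calls.mask)

    def test_concordance_three_pairs_three_rows(self, tmp_path):
        # 3 measures -> C(3,2) = 3 unordered pairs, one summary row each
        tables = [
            ox.ConcordanceTable(pair=p, tissue="healthy",
                                axis="per_probe_across_samples", statistic="S",
                                values=pd.Series(dtype=float), expectation=e,
                                expectation_method="empirical_mean")
            for p, e in [(("delta_beta", "delta_m_inf"), 0.8),
                         (("delta_beta", "delta_h"), 0.79),
                         (("delta_m_inf", "delta_h"), 0.81)]
        ]
        path = tmp_path / "conc.tsv"
        ox.write_table(tables, path)
        frame = pd.read_csv(path, sep="\t")
        assert len(frame) == 3
        back = ox.read_concordance(path)
        assert {t.pair for t in back} == {t.pair for t in tables}
        assert all(t.expectation is not None for t in back)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 8), st.integers(1, 5),
       st.floats(0.0, 0.9))
def test_round_trip_property(tmp_path_factory, seed, n_probes, n_samples, mask_rate):
    """read(write(x)) reproduces unmasked values within 1e-12 and the mask exactly."""
    rng = np.random.default_rng(seed)
    mask = rng.random((n_probes, n_samples)) >= mask_rate
    values = rng.normal(0, 3, (n_probes, n_samples))
    m = ox.MeasureMatrix("delta_m", values=np.where(mask, values, np.nan), mask=mask,
                         probe_ids=[f"p{i}" for i in range(n_probes)],
                         sample_ids=[f"s{j}" for j in range(n_samples)], alpha=0.0)
    path = tmp_path_factory.mktemp("rt") / "m.tsv"
    ox.write_table(m, path)
    back = ox.read_measure_matrix(path)
    np.testing.assert_array_equal(back.mask, mask)
    if mask.any():
        np.testing.assert_allclose(back.values[mask], values[mask], rtol=1e-12, atol=0)
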