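"""Core data containers and delimited-table I/O for paired BS/oxBS intensities.

The central object is :class:`IntensityPanel`, which holds the four
probe x sample intensity matrices produced by a paired bisulfite (BS) /
oxidative-bisulfite (oxBS) methylation-array experiment:

* ``M_bs`` / ``U_bs``  -- methylated / unmethylated allele intensities after
  plain bisulfite conversion (reads 5mC + 5hmC as methylated);
* ``M_oxbs`` / ``U_oxbs`` -- the same after oxidative bisulfite conversion
  (5hmC is oxidised away, so only 5mC reads as methylated).

All containers carry a boolean ``mask`` of the same shape as the data, with
``True`` meaning *valid / defined*.  Invalid cells (negative, non-numeric or
missing on input; undefined denominators downstream) are masked out and every
operation propagates masks by logical AND.  Masked cells are serialised as
``"NA"``.

Tables on disk are probes-in-rows, samples-in-columns, with a header row of
sample IDs and the probe ID in the first column -- the layout of matrices
exported from minfi-style preprocessing of 450k arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oxbscreen")

TISSUES = ("healthy", "cancer", "unspecified")

#: Canonical names of the four intensity matrices in a panel.
ROLES = ("M_bs", "U_bs", "M_oxbs", "U_oxbs")

MEASURE_NAMES = (
    "beta",
    "m",
    "delta_beta",
    "delta_m",
    "delta_m_inf",
    "delta_h",
    "naive_5hmc",
)

#: Measures parameterised by the intensity offset alpha.
ALPHA_MEASURES = frozenset({"beta", "m", "delta_beta", "delta_m"})

MISSING_TOKEN = "NA"
_INPUT_MISSING = ["NA", "NaN", "nan", ""]


class PanelError(ValueError):
    """Malformed panel, table or container."""


class AlignmentError(PanelError):
    """Probe/sample IDs differ between the four intensity tables."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise PanelError(f"duplicate {what}: {dupes[:5]}")
    return ids


def _as_matrix(x, shape, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise PanelError(f"{what} has shape {arr.shape}, expected {shape}")
    return arr


@dataclass
class IntensityPanel:
    """Aligned probe x sample intensity matrices for one tissue.

    Parameters
    ----------
    probe_ids, sample_ids
        Opaque identifiers; duplicates are rejected.
    tissue
        One of ``"healthy"``, ``"cancer"``, ``"unspecified"``.
    M_bs, U_bs, M_oxbs, U_oxbs
        Non-negative fluorescence intensities, shape (n_probes, n_samples).
    mask
        ``True`` where the entry is valid in *all four* matrices.  Defaults
        to all-valid.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    M_bs: np.ndarray
    U_bs: np.ndarray
    M_oxbs: np.ndarray
    U_oxbs: np.ndarray
    tissue: str = "unspecified"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probe_ids = _check_ids(self.probe_ids, "probe IDs")
        self.sample_ids = _check_ids(self.sample_ids, "sample IDs")
        if self.tissue not in TISSUES:
            raise PanelError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        shape = (len(self.probe_ids), len(self.sample_ids))
        self.M_bs = _as_matrix(self.M_bs, shape, "M_bs")
        self.U_bs = _as_matrix(self.U_bs, shape, "U_bs")
        self.M_oxbs = _as_matrix(self.M_oxbs, shape, "M_oxbs")
        self.U_oxbs = _as_matrix(self.U_oxbs, shape, "U_oxbs")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise PanelError(f"mask has shape {self.mask.shape}, expected {shape}")
        for role in ROLES:
            vals = self.intensity(role)[self.mask]
            if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
                raise PanelError(f"unmasked {role} intensities must be finite and >= 0")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_probes, self.n_samples)

    def intensity(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise PanelError(f"unknown intensity role {role!r}; expected one of {ROLES}")
        return getattr(self, role)

    def frame(self, role: str) -> pd.DataFrame:
        return pd.DataFrame(self.intensity(role), index=self.probe_ids, columns=self.sample_ids)

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Global intensities (M+U) for the BS and oxBS arms."""
        return self.M_bs + self.U_bs, self.M_oxbs + self.U_oxbs


@dataclass
class MeasureMatrix:
    """Probe x sample values of one named 5hmC measure.

    ``alpha`` is present exactly for the offset-dependent measures
    (``beta``, ``m``, ``delta_beta``, ``delta_m``).  ``noise_flag`` marks
    entries that are defined but interpreted as measurement noise (negative
    values of the 5hmC proportion measure).
    """

    measure_name: str
    values: np.ndarray
    mask: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    alpha: float | None = None
    noise_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.measure_name not in MEASURE_NAMES:
            raise PanelError(f"unknown measure {self.measure_name!r}")
        needs_alpha = self.measure_name in ALPHA_MEASURES
        if needs_alpha and self.alpha is None:
            raise PanelError(f"measure {self.measure_name!r} requires alpha")
        if not needs_alpha and self.alpha is not None:
            raise PanelError(f"measure {self.measure_name!r} does not take alpha")
        if self.alpha is not None and self.alpha < 0:
            raise PanelError("alpha must be >= 0")
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise PanelError("values and mask shapes differ")
        self.probe_ids = _check_ids(self.probe_ids, "probe IDs")
        self.sample_ids = _check_ids(self.sample_ids, "sample IDs")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise PanelError("values shape does not match probe/sample IDs")
        v = self.values[self.mask]
        if v.size and not np.all(np.isfinite(v)):
            raise PanelError("unmasked measure values must be finite")
        if self.measure_name == "delta_beta" and v.size and (v.min() < -1 or v.max() > 1):
            raise PanelError("delta_beta values must lie in [-1, 1]")
        if self.measure_name == "delta_h" and v.size and v.max() > 1:
            raise PanelError("delta_h values must be <= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class CallMatrix:
    """Binary screening calls: ``True`` flags a probe/sample as hydroxymethylated.

    A call is positive iff the unmasked measure value is *strictly* greater
    than ``threshold`` (exact zeros are non-positive).
    """

    measure_name: str
    calls: np.ndarray
    mask: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.calls.shape != self.mask.shape:
            raise PanelError("calls and mask shapes differ")
        self.probe_ids = _check_ids(self.probe_ids, "probe IDs")
        self.sample_ids = _check_ids(self.sample_ids, "sample IDs")
        if self.calls.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise PanelError("calls shape does not match probe/sample IDs")
        if not np.isfinite(self.threshold):
            raise PanelError("threshold must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.probe_ids, columns=self.sample_ids)


#: Axes over which pairwise concordance is aggregated.
CONCORDANCE_AXES = ("per_probe_across_samples", "per_sample_across_probes")
CONCORDANCE_STATISTICS = ("S", "SH", "SE_r", "SP_r", "FDR_r")
EXPECTATION_METHODS = ("empirical_mean", "independence_null")


@dataclass
class ConcordanceTable:
    """Unit-wise values and expectation of one concordance statistic for one
    pair of measures.

    ``pair`` is unordered for the symmetric similarity coefficients (S, SH)
    and ordered as ``(x1, x2)`` meaning ``stat(x1 | x2)`` for the relative
    accuracy statistics.  ``degenerate`` flags units with no jointly-positive
    calls where S is nevertheless positive -- the situation in which the
    simple matching coefficient can be misleading and the Hamann coefficient
    should be consulted.
    """

    pair: tuple[str, str]
    tissue: str
    axis: str
    statistic: str
    values: pd.Series
    expectation: float | None = None
    expectation_method: str | None = None
    degenerate: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.axis not in CONCORDANCE_AXES:
            raise PanelError(f"unknown axis {self.axis!r}")
        if self.statistic not in CONCORDANCE_STATISTICS:
            raise PanelError(f"unknown statistic {self.statistic!r}")
        if self.tissue not in TISSUES:
            raise PanelError(f"unknown tissue {self.tissue!r}")
        if self.expectation_method is not None and self.expectation_method not in EXPECTATION_METHODS:
            raise PanelError(f"unknown expectation method {self.expectation_method!r}")
        v = pd.Series(self.values, dtype=float)
        if self.statistic == "S" and v.size and (v.min() < 0 or v.max() > 1):
            raise PanelError("S values must lie in [0, 1]")
        if self.statistic == "SH" and v.size and (v.min() < -1 or v.max() > 1):
            raise PanelError("SH values must lie in [-1, 1]")
        if self.statistic in ("SE_r", "SP_r", "FDR_r") and v.size:
            w = v.dropna()
            if w.size and (w.min() < 0 or w.max() > 1):
                raise PanelError(f"{self.statistic} values must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame, one row per unit (or one summary row if empty)."""
        if len(self.values):
            units = list(self.values.index.astype(str))
            vals = self.values.to_numpy()
        else:
            units, vals = [MISSING_TOKEN], [np.nan]
        return pd.DataFrame(
            {
                "measure_1": self.pair[0],
                "measure_2": self.pair[1],
                "tissue": self.tissue,
                "axis": self.axis,
                "statistic": self.statistic,
                "expectation": np.nan if self.expectation is None else self.expectation,
                "expectation_method": self.expectation_method or MISSING_TOKEN,
                "unit": units,
                "value": vals,
            }
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _normalise_role(key: str) -> str:
    k = key.strip().lower().replace("-", "_")
    for role in ROLES:
        if k == role.lower():
            return role
    raise PanelError(f"unknown intensity role {key!r}; expected one of {ROLES}")


def _read_matrix(path: Path) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Read one intensity table; return (numeric frame, validity mask, n_invalid)."""
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False, na_values=[])
    raw.index = raw.index.astype(str)
    cells = raw.to_numpy()
    stripped = np.char.strip(cells.astype(str))
    missing = np.isin(stripped, _INPUT_MISSING)
    numeric = pd.to_numeric(pd.Series(stripped.ravel()), errors="coerce").to_numpy().reshape(cells.shape)
    non_numeric = np.isnan(numeric) & ~missing
    negative = numeric < 0
    valid = ~missing & ~non_numeric & ~negative
    numeric = np.where(valid, numeric, np.nan)
    n_invalid = int(non_numeric.sum() + negative.sum())
    frame = pd.DataFrame(numeric, index=raw.index, columns=raw.columns)
    return frame, valid, n_invalid


def read_panel(path_map: Mapping[str, str | Path], tissue: str = "unspecified") -> IntensityPanel:
    """Read the four intensity tables of one tissue into an aligned panel.

    ``path_map`` maps the four roles (``M_bs``, ``U_bs``, ``M_oxbs``,
    ``U_oxbs``; case-insensitive) to TSV/CSV files with probe IDs in the
    first column and sample IDs in the header.  Negative or non-numeric cells
    are masked (with a logged count); probes or samples present in only some
    of the four files raise :class:`AlignmentError`.
    """
    paths: dict[str, Path] = {}
    for key, value in path_map.items():
        paths[_normalise_role(key)] = Path(value)
    for role in ROLES:
        if role not in paths:
            raise PanelError(f"path for intensity role {role!r} is missing")
        if not paths[role].exists():
            raise PanelError(f"file for intensity role {role!r} not found: {paths[role]}")

    frames: dict[str, pd.DataFrame] = {}
    valids: dict[str, np.ndarray] = {}
    for role in ROLES:
        frame, valid, n_invalid = _read_matrix(paths[role])
        if n_invalid:
            logger.warning("%s: masked %d invalid cell(s) in %s", role, n_invalid, paths[role])
        frames[role] = frame
        valids[role] = valid

    ref_role = ROLES[0]
    probe_ids = list(frames[ref_role].index)
    sample_ids = list(frames[ref_role].columns)
    offenders = []
    for role in ROLES[1:]:
        f = frames[role]
        if set(f.index) != set(probe_ids) or set(f.columns) != set(sample_ids):
            missing_p = sorted(set(probe_ids) ^ set(f.index))
            missing_s = sorted(set(sample_ids) ^ set(f.columns))
            offenders.append(f"{role}: probes {missing_p[:5]} samples {missing_s[:5]}")
        elif list(f.index) != probe_ids or list(f.columns) != sample_ids:
            frames[role] = f.loc[probe_ids, sample_ids]
            valids[role] = pd.DataFrame(valids[role], index=f.index, columns=f.columns).loc[
                probe_ids, sample_ids
            ].to_numpy()
    if offenders:
        raise AlignmentError("intensity tables are not aligned -- " + "; ".join(offenders))

    mask = np.logical_and.reduce([valids[r] for r in ROLES])
    panel = IntensityPanel(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        tissue=tissue,
        M_bs=frames["M_bs"].to_numpy(),
        U_bs=frames["U_bs"].to_numpy(),
        M_oxbs=frames["M_oxbs"].to_numpy(),
        U_oxbs=frames["U_oxbs"].to_numpy(),
        mask=mask,
    )
    logger.info(
        "read panel: %d probes x %d samples (%s), %d masked entr%s",
        panel.n_probes, panel.n_samples, tissue,
        int((~mask).sum()), "y" if (~mask).sum() == 1 else "ies",
    )
    return panel


def write_panel(panel: IntensityPanel, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write the four intensity matrices as TSVs; masked entries become NA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for role in ROLES:
        frame = panel.frame(role).where(panel.mask)
        path = out_dir / f"{prefix}{role}.tsv"
        frame.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)
        written[role] = path
    return written


# ---------------------------------------------------------------------------
# Writing / round-tripping result tables
# ---------------------------------------------------------------------------


def _write_matrix_like(frame: pd.DataFrame, path: Path, header: dict[str, str]) -> None:
    try:
        with open(path, "w") as fh:
            for key, value in header.items():
                fh.write(f"# {key}={value}\n")
            frame.to_csv(fh, sep=_sep_for(path), na_rep=MISSING_TOKEN)
    except OSError as exc:
        raise PanelError(f"cannot write {path}: {exc}") from exc


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            n += 1
    return meta, n


def write_table(result, path: str | Path) -> None:
    """Serialise a MeasureMatrix, CallMatrix or ConcordanceTable(s) to disk.

    Output is delimited text (TSV unless the path ends in ``.csv``) with a
    stable column order and ``NA`` for masked entries; metadata rides in
    ``# key=value`` comment lines so the corresponding reader can round-trip
    the object.
    """
    path = Path(path)
    if isinstance(result, MeasureMatrix):
        header = {"type": "measure", "measure": result.measure_name}
        if result.alpha is not None:
            header["alpha"] = repr(float(result.alpha))
        frame = result.frame().where(result.mask)
        _write_matrix_like(frame, path, header)
    elif isinstance(result, CallMatrix):
        header = {
            "type": "calls",
            "measure": result.measure_name,
            "threshold": repr(float(result.threshold)),
        }
        frame = result.frame().astype(int).where(result.mask)
        _write_matrix_like(frame, path, header)
    elif isinstance(result, ConcordanceTable):
        write_table([result], path)
    elif isinstance(result, (list, tuple)) and all(isinstance(t, ConcordanceTable) for t in result):
        frames = [t.to_frame() for t in result]
        combined = pd.concat(frames, ignore_index=True)
        try:
            combined.to_csv(path, sep=_sep_for(path), index=False, na_rep=MISSING_TOKEN)
        except OSError as exc:
            raise PanelError(f"cannot write {path}: {exc}") from exc
    else:
        raise PanelError(f"cannot serialise object of type {type(result).__name__}")


def read_measure_matrix(path: str | Path) -> MeasureMatrix:
    path = Path(path)
    meta, _ = _read_header(path)
    if meta.get("type") != "measure":
        raise PanelError(f"{path} is not a measure table")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#",
                        na_values=_INPUT_MISSING, keep_default_na=False)
    values = frame.to_numpy(dtype=float)
    mask = np.isfinite(values)
    alpha = float(meta["alpha"]) if "alpha" in meta else None
    return MeasureMatrix(
        measure_name=meta["measure"],
        values=np.where(mask, values, np.nan),
        mask=mask,
        probe_ids=list(frame.index.astype(str)),
        sample_ids=list(frame.columns.astype(str)),
        alpha=alpha,
    )


def read_call_matrix(path: str | Path) -> CallMatrix:
    path = Path(path)
    meta, _ = _read_header(path)
    if meta.get("type") != "calls":
        raise PanelError(f"{path} is not a call table")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#",
                        na_values=_INPUT_MISSING, keep_default_na=False)
    values = frame.to_numpy(dtype=float)
    mask = np.isfinite(values)
    return CallMatrix(
        measure_name=meta["measure"],
        calls=np.where(mask, values, 0).astype(bool),
        mask=mask,
        probe_ids=list(frame.index.astype(str)),
        sample_ids=list(frame.columns.astype(str)),
        threshold=float(meta.get("threshold", 0.0)),
    )


def read_concordance(path: str | Path) -> list[ConcordanceTable]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), na_values=_INPUT_MISSING,
                        keep_default_na=False)
    tables: list[ConcordanceTable] = []
    keys = ["measure_1", "measure_2", "tissue", "axis", "statistic"]
    for _, group in frame.groupby(keys, sort=False):
        row = group.iloc[0]
        units = group["unit"].astype(str)
        vals = pd.Series(group["value"].to_numpy(dtype=float), index=units)
        if len(vals) == 1 and units.iloc[0] == MISSING_TOKEN and np.isnan(vals.iloc[0]):
            vals = pd.Series(dtype=float)
        method = row["expectation_method"]
        tables.append(
            ConcordanceTable(
                pair=(str(row["measure_1"]), str(row["measure_2"])),
                tissue=str(row["tissue"]),
                axis=str(row["axis"]),
                statistic=str(row["statistic"]),
                values=vals,
                expectation=None if pd.isna(row["expectation"]) else float(row["expectation"]),
                expectation_method=None if method in (MISSING_TOKEN, "", None) else str(method),
            )
        )
    return tables
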