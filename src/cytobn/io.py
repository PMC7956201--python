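"""Cell-level intensity I/O and T-cell subset gating.

Reads compensated fluorescence intensity matrices from FCS 3.0/3.1 files or
delimited text, attaches per-cell clinical annotations (patient, timepoint
day, responder label, tumor-size change), and stratifies cells into the four
major T-cell subsets (naive/non-naive x CD4/CD8) by threshold gating on
CD4, CD8, CCR7 and CD45RA.

Intensities are taken as exported from the cytometry software: already
compensated, untransformed.  Negative values (possible after compensation)
are accepted unchanged.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellMatrix",
    "PanelCutoffs",
    "CellTypeRule",
    "CELL_TYPE_RULES",
    "PANEL_CUTOFFS",
    "GATING_MARKERS",
    "RESPONSE_TSIZE_THRESHOLD",
    "FormatError",
    "read_fcs",
    "write_fcs",
    "read_table",
    "stratify_cell_type",
    "derive_response",
]

#: Gating markers, in the bit order used by the membership patterns.
GATING_MARKERS = ("CD4", "CD8", "CCR7", "CD45RA")

#: Tumor radius change (percent) below which a patient is a responder.
RESPONSE_TSIZE_THRESHOLD = -25.0

#: Required per-cell annotation fields.
ANNOTATION_FIELDS = ("patient_id", "day", "response", "tsize")

#: Study timepoints (days relative to therapy start).
STUDY_DAYS = (1, 21)


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class CellMatrix:
    """Cells x markers continuous intensities with per-cell annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        One row per cell, one column per marker; nonnegative in typical
        exports but negatives are allowed (compensation artifacts).
    annotations : pandas.DataFrame
        Per-cell records aligned with ``values`` (same index), with columns
        ``patient_id`` (str), ``day`` (int), ``response`` (bool-like,
        True = responder), ``tsize`` (float, percent tumor radius change).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.values) != len(self.annotations):
            raise ValueError(
                f"{len(self.values)} cells but {len(self.annotations)} annotation rows"
            )
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate marker names: {dupes}")
        missing = [c for c in ANNOTATION_FIELDS if c not in self.annotations.columns]
        if missing:
            raise ValueError(f"missing annotation fields: {missing}")
        days = set(self.annotations["day"].unique().tolist())
        bad = days - set(STUDY_DAYS)
        if bad:
            raise ValueError(f"days {sorted(bad)} outside study timepoints {STUDY_DAYS}")
        self.annotations = self.annotations.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)

    @property
    def marker_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def select(self, mask: np.ndarray) -> "CellMatrix":
        """Row subset, annotations kept aligned."""
        return CellMatrix(self.values.loc[mask].reset_index(drop=True),
                          self.annotations.loc[mask].reset_index(drop=True))

    def drop_markers(self, markers) -> "CellMatrix":
        return CellMatrix(self.values.drop(columns=list(markers)), self.annotations.copy())


@dataclass(frozen=True)
class PanelCutoffs:
    """High/low gating thresholds for one FACS panel."""

    panel_name: str
    thresholds: dict

    def __post_init__(self) -> None:
        if set(self.thresholds) != set(GATING_MARKERS):
            raise ValueError(
                f"thresholds must cover exactly {GATING_MARKERS}, got {sorted(self.thresholds)}"
            )


@dataclass(frozen=True)
class CellTypeRule:
    """A T-cell subset defined by 4-bit (CD4, CD8, CCR7, CD45RA) patterns."""

    name: str
    patterns: frozenset

    def __post_init__(self) -> None:
        for p in self.patterns:
            if len(p) != 4 or set(p) - {"0", "1"}:
                raise ValueError(f"bad pattern {p!r}: expected 4-bit string")


#: Membership rules for the four major T-cell subsets.
CELL_TYPE_RULES = {
    "NaiveCD4": CellTypeRule("NaiveCD4", frozenset({"1011"})),
    "NaiveCD8": CellTypeRule("NaiveCD8", frozenset({"0111"})),
    "NonNaiveCD4": CellTypeRule("NonNaiveCD4", frozenset({"1010", "1001", "1000"})),
    "NonNaiveCD8": CellTypeRule("NonNaiveCD8", frozenset({"0110", "0101", "0100"})),
}

#: Panel-specific cutoffs (panels are calibrated differently).
PANEL_CUTOFFS = {
    "Checkpoint": PanelCutoffs("Checkpoint",
                               {"CD4": 1500.0, "CD8": 750.0, "CCR7": 150.0, "CD45RA": 400.0}),
    "Adaptive": PanelCutoffs("Adaptive",
                             {"CD4": 1000.0, "CD8": 1000.0, "CCR7": 150.0, "CD45RA": 1000.0}),
}


def derive_response(tsize) -> np.ndarray:
    """Responder label from percent tumor radius change (strict < -25)."""
    return np.asarray(tsize, dtype=float) < RESPONSE_TSIZE_THRESHOLD


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1
# ---------------------------------------------------------------------------

_FCS_VERSIONS = (b"FCS3.0", b"FCS3.1")


def _parse_text_segment(raw: bytes) -> dict:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Delimiter escaping (doubled delimiters) is not handled; keys/values in
    # instrument exports do not normally contain the delimiter.
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of delimited tokens")
    kw = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("ascii", "replace").strip().upper()
        kw[key] = parts[i + 1].decode("ascii", "replace").strip()
    return kw


def read_fcs(path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file into an events x parameters DataFrame.

    Columns are named from the $PnS keyword, falling back to $PnN.  No
    transformation or compensation is applied beyond what the file stores.
    Annotations are not present in FCS files; callers attach them separately
    (see :func:`read_table` for the sidecar convention).
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 58:
        raise FormatError("file too short for an FCS header")
    version = data[0:6]
    if version not in _FCS_VERSIONS:
        raise FormatError(f"unsupported FCS version {version!r} in header segment")
    try:
        text_start = int(data[10:18])
        text_end = int(data[18:26])
        data_start = int(data[26:34])
        data_end = int(data[34:42])
    except ValueError as exc:
        raise FormatError(f"non-numeric offsets in header segment: {exc}") from None
    kw = _parse_text_segment(data[text_start:text_end + 1])
    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"]
        byteord = kw["$BYTEORD"]
    except KeyError as exc:
        raise FormatError(f"missing required keyword {exc} in TEXT segment") from None

    names = []
    widths = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N")
        if not name:
            raise FormatError(f"missing $P{i}N keyword in TEXT segment")
        names.append(name)
        try:
            widths.append(int(kw[f"$P{i}B"]))
        except KeyError:
            raise FormatError(f"missing $P{i}B keyword in TEXT segment") from None
    if len(set(names)) != len(names):
        raise FormatError(f"duplicate parameter names in TEXT segment: {names}")

    little = byteord.startswith("1")
    order = "<" if little else ">"
    raw = data[data_start:data_end + 1]
    if datatype == "F":
        if any(w != 32 for w in widths):
            raise FormatError("$DATATYPE/F requires 32-bit $PnB in TEXT segment")
        arr = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=order + "f4")
    elif datatype == "D":
        if any(w != 64 for w in widths):
            raise FormatError("$DATATYPE/D requires 64-bit $PnB in TEXT segment")
        arr = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=order + "f8")
    elif datatype == "I":
        if any(w != widths[0] or w not in (16, 32) for w in widths):
            raise FormatError("$DATATYPE/I supported only for uniform 16/32-bit $PnB")
        arr = np.frombuffer(raw[: widths[0] // 8 * n_par * n_tot],
                            dtype=f"{order}u{widths[0] // 8}")
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r} in TEXT segment")
    if arr.size != n_par * n_tot:
        raise FormatError(
            f"DATA segment holds {arr.size} values, expected $PAR*$TOT = {n_par * n_tot}"
        )
    mat = arr.reshape(n_tot, n_par).astype(np.float64)
    return pd.DataFrame(mat, columns=names)


def write_fcs(path, values: pd.DataFrame) -> None:
    """Write an events x parameters table as a minimal FCS 3.1 file.

    Single-precision floating-point DATA segment, little-endian.  Used to
    build round-trip fixtures; not a general-purpose exporter.
    """
    n_tot, n_par = values.shape
    d = "/"
    kw = {
        "$DATATYPE": "F", "$BYTEORD": "1,2,3,4", "$MODE": "L",
        "$PAR": str(n_par), "$TOT": str(n_tot),
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
    }
    for i, name in enumerate(values.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    payload = values.to_numpy(dtype="<f4").tobytes()

    # Offsets depend on TEXT length; keywords $BEGINDATA/$ENDDATA are sized
    # with fixed-width values so the layout converges in one pass.
    for _ in range(3):
        text = d + d.join(f"{k}{d}{v}" for k, v in kw.items()) + d
        text_start = 58
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(payload) - 1
        kw["$BEGINDATA"] = str(data_start)
        kw["$ENDDATA"] = str(data_end)
        if "$BEGINDATA" in text:
            break
    header = b"FCS3.1    " + b"".join(
        f"{x:8d}".encode() for x in
        (text_start, text_end,
         data_start if data_end <= 99_999_999 else 0,
         data_end if data_end <= 99_999_999 else 0,
         0, 0)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(payload)


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def read_table(path, marker_columns, annotation_columns, sep=None) -> CellMatrix:
    """Read a delimited text file with header into a :class:`CellMatrix`.

    Parameters
    ----------
    marker_columns : list of str
        Columns holding marker intensities, in panel order.
    annotation_columns : dict
        Maps annotation fields (``patient_id``, ``day``, ``tsize`` and
        optionally ``response``) to column names.  If ``response`` is
        absent it is derived as ``tsize < -25``.
    sep : str, optional
        Field delimiter; sniffed from the header line (comma vs tab) when
        omitted.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    required = list(marker_columns) + [annotation_columns[k]
                                       for k in ("patient_id", "day", "tsize")]
    if "response" in annotation_columns:
        required.append(annotation_columns["response"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")

    values = df[list(marker_columns)].copy()
    for col in marker_columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        if numeric.isna().any() and not values[col].isna().any():
            bad = int(np.flatnonzero(numeric.isna() & values[col].notna())[0])
            raise FormatError(f"non-numeric intensity in column {col!r} at row {bad}")
        values[col] = numeric.astype(float)

    ann = pd.DataFrame({
        "patient_id": df[annotation_columns["patient_id"]].astype(str),
        "day": df[annotation_columns["day"]].astype(int),
        "tsize": pd.to_numeric(df[annotation_columns["tsize"]], errors="raise").astype(float),
    })
    if "response" in annotation_columns:
        ann["response"] = df[annotation_columns["response"]].astype(bool)
    else:
        ann["response"] = derive_response(ann["tsize"])
    return CellMatrix(values, ann)


def write_table(path, cells: CellMatrix, sep=",") -> None:
    """Write a :class:`CellMatrix` in the dialect :func:`read_table` reads."""
    out = pd.concat([cells.values, cells.annotations], axis=1)
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

def _patterns(cells: CellMatrix, cutoffs: PanelCutoffs) -> np.ndarray:
    missing = [m for m in GATING_MARKERS if m not in cells.values.columns]
    if missing:
        raise ValueError(f"gating markers missing from matrix: {missing}")
    bits = np.column_stack([
        (cells.values[m].to_numpy() >= cutoffs.thresholds[m]).astype(np.uint8)
        for m in GATING_MARKERS
    ])
    return bits


def stratify_cell_type(cells: CellMatrix, cutoffs: PanelCutoffs,
                       rule: CellTypeRule, drop_gating: bool = True) -> CellMatrix:
    """Keep cells whose 4-bit (CD4, CD8, CCR7, CD45RA) high/low pattern
    belongs to ``rule``, then drop the four gating markers.

    A bit is 1 iff intensity >= cutoff.  Cells matching none of the four
    canonical rules (e.g. 1111, 0000) are simply not selected by any rule.
    ``drop_gating=False`` keeps the gating columns (e.g. to re-gate or
    inspect the thresholds).
    """
    bits = _patterns(cells, cutoffs)
    want = np.array([[int(c) for c in p] for p in sorted(rule.patterns)], dtype=np.uint8)
    mask = (bits[:, None, :] == want[None, :, :]).all(axis=2).any(axis=1)
    if not mask.any():
        warnings.warn(f"no cells match cell-type rule {rule.name}", stacklevel=2)
    kept = cells.select(mask)
    if not drop_gating:
        return kept
    return kept.drop_markers([m for m in GATING_MARKERS if m in kept.values.columns])
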