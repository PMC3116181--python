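"""Input/output for composition, activity and z-scale tables.

All tabular data are plain delimited text (comma by default, tab via
``sep="\\t"``) with one header row and the sample identifier in the first
column. Amino-acid compositions are percentages per sample over the 18
labels produced by acid-hydrolysis amino-acid analysis (Asn+Asp pooled as
ASX, Gln+Glu pooled as GLX), so each row sums to ~100.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

#: The 18 amino-acid labels of a pooled composition analysis, in the
#: canonical column order used throughout the package.
AA_LABELS: tuple[str, ...] = (
    "ASX", "THR", "SER", "GLX", "PRO", "GLY", "ALA", "CYS", "VAL",
    "MET", "ILE", "LEU", "TYR", "PHE", "HIS", "LYS", "ARG", "TRP",
)

#: The 20 standard residues expected in a raw (unpooled) z-scale table.
STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Recognised activity names and their units.
ACTIVITY_UNITS: dict[str, str] = {
    "dpph": "percent scavenging",
    "frap": "absorbance at 700 nm",
    "h2o2": "percent scavenging",
    "superoxide": "percent scavenging",
}

ROW_SUM_BOUNDS = (95.0, 105.0)

# Footnote orderings that any admissible pooled z-scale table must satisfy
# (most-electronic residues, most-hydrophobic residues, least-bulky residues).
_ZSCALE_ORDERINGS = (
    ("z3", "descending", ("CYS", "PRO", "ASX", "HIS", "TRP"),
     "Cys > Pro > Asx > His > Trp"),
    ("z1", "ascending", ("PHE", "TRP", "ILE", "LEU", "VAL", "MET", "TYR"),
     "Phe < Trp < Ile < Leu < Val < Met < Tyr"),
    ("z2", "ascending", ("GLY", "VAL", "THR", "ALA", "ILE", "SER", "LEU", "CYS"),
     "Gly < Val < Thr < Ala < Ile < Ser < Leu < Cys"),
)


class TableFormatError(ValueError):
    """A delimited table does not have the required shape or columns."""


class TableValidationError(ValueError):
    """A structurally sound table violates a domain invariant."""


class RowSumWarning(UserWarning):
    """A composition row sums outside the plausible percentage window."""


def _read_delimited(source: str | Path | IO[str], sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(source, sep=sep, comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c).strip().upper() for c in df.columns]
    return df


def validate_composition(values: pd.DataFrame, strict_row_sum: bool = False) -> None:
    """Check composition invariants: complete AA columns, non-negative
    percentages, no missing cells, row sums within ``ROW_SUM_BOUNDS``.

    Row-sum violations warn by default (partial hydrolysate panels may
    legitimately omit residues); ``strict_row_sum=True`` raises instead.
    """
    missing = [a for a in AA_LABELS if a not in values.columns]
    if missing:
        raise TableFormatError(f"missing amino-acid column(s): {', '.join(missing)}")
    unknown = [c for c in values.columns if c not in AA_LABELS]
    if unknown:
        raise TableFormatError(f"unknown amino-acid column(s): {', '.join(unknown)}")
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate sample id(s): {dups}")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise TableFormatError(
            f"missing value at sample {values.index[r]!r}, column {values.columns[c]!r}"
        )
    if (values.to_numpy() < 0).any():
        r, c = np.argwhere((values < 0).to_numpy())[0]
        raise TableValidationError(
            f"negative composition at sample {values.index[r]!r}, "
            f"column {values.columns[c]!r}"
        )
    sums = values.sum(axis=1)
    bad = sums[(sums < ROW_SUM_BOUNDS[0]) | (sums > ROW_SUM_BOUNDS[1])]
    if len(bad):
        msg = "; ".join(f"sample {i!r} sums to {s:.2f}%" for i, s in bad.items())
        if strict_row_sum:
            raise TableValidationError(f"row sum outside {ROW_SUM_BOUNDS}: {msg}")
        warnings.warn(f"row sum outside {ROW_SUM_BOUNDS}: {msg}", RowSumWarning,
                      stacklevel=2)


def load_composition_table(
    source: str | Path | IO[str],
    sep: str = ",",
    strict_row_sum: bool = False,
) -> pd.DataFrame:
    """Read a samples × 18 amino-acid percent-composition table.

    The header must name all 18 pooled amino-acid codes (order-insensitive,
    case-insensitive); the first column holds sample ids. Returns a
    DataFrame with columns in canonical :data:`AA_LABELS` order.
    """
    try:
        df = _read_delimited(source, sep=sep)
    except ValueError as exc:  # non-numeric cells surface here
        raise TableFormatError(f"could not parse composition table: {exc}") from exc
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableFormatError(
                f"non-numeric value in column {col!r} at sample {row!r}"
            )
    validate_composition(df, strict_row_sum=strict_row_sum)
    return df[list(AA_LABELS)].astype(float)


def pool_zscales(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse a 20-residue z-scale table to the 18 pooled labels.

    ASX is the arithmetic mean of the ASN and ASP records, GLX of GLN and
    GLU, matching how acid hydrolysis reports these residues.
    """
    required = {"z1", "z2", "z3"}
    cols = {c.lower(): c for c in raw.columns}
    if not required.issubset(cols):
        raise TableFormatError(
            f"z-scale table needs columns z1, z2, z3; got {list(raw.columns)}"
        )
    raw = raw.rename(columns={cols[k]: k for k in required})
    raw.index = raw.index.str.upper()
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate amino-acid row(s): {dups}")
    missing = [a for a in STANDARD_AA if a not in raw.index]
    if missing:
        raise TableFormatError(f"missing amino acid(s): {', '.join(missing)}")
    pooled = {}
    for aa in AA_LABELS:
        if aa == "ASX":
            rec = raw.loc[["ASN", "ASP"], ["z1", "z2", "z3"]].mean()
        elif aa == "GLX":
            rec = raw.loc[["GLN", "GLU"], ["z1", "z2", "z3"]].mean()
        else:
            rec = raw.loc[aa, ["z1", "z2", "z3"]]
        pooled[aa] = rec.astype(float)
    return pd.DataFrame(pooled).T[["z1", "z2", "z3"]]


def validate_zscale_orderings(pooled: pd.DataFrame) -> None:
    """Verify the qualitative orderings any plausible 3-z table shows:
    electronic character (z3) led by Cys, hydrophobicity (low z1) led by
    Phe, and small side-chain bulk (low z2) led by Gly."""
    for col, direction, order, footnote in _ZSCALE_ORDERINGS:
        vals = pooled.loc[list(order), col].to_numpy()
        ok = np.all(np.diff(vals) < 0) if direction == "descending" else np.all(
            np.diff(vals) > 0
        )
        if not ok:
            raise TableValidationError(
                f"{col} ordering violated; expected {footnote!r}"
            )


def load_zscale_table(source: str | Path | IO[str], sep: str = ",") -> pd.DataFrame:
    """Read a 20-residue (z1, z2, z3) table and return the pooled 18-label
    table with ordering invariants verified."""
    raw = _read_delimited(source, sep=sep)
    pooled = pool_zscales(raw)
    validate_zscale_orderings(pooled)
    return pooled


def load_activity_table(
    source: str | Path | IO[str],
    activity: str | None = None,
    sep: str = ",",
) -> pd.Series:
    """Read a per-sample activity vector (one value column, or pick one of
    several by name). Units are tagged from :data:`ACTIVITY_UNITS` when the
    name is recognised."""
    df = _read_delimited(source, sep=sep)
    if activity is None:
        if df.shape[1] != 1:
            raise TableFormatError(
                f"activity name required to choose among columns {list(df.columns)}"
            )
        activity = df.columns[0]
    activity = activity.lower()
    cols = {c.lower(): c for c in df.columns}
    if activity not in cols:
        raise TableFormatError(f"activity {activity!r} not in {list(df.columns)}")
    s = df[cols[activity]].dropna().astype(float)
    s.name = activity
    s.attrs["units"] = ACTIVITY_UNITS.get(activity, "unknown")
    if s.empty:
        raise TableValidationError(f"activity {activity!r} has no values")
    return s


@dataclass
class Dataset:
    """A composition matrix plus optional activities and a z-scale table.

    ``activities`` maps activity name to a per-sample Series whose index is
    a subset of the composition's sample ids (assays may cover fewer
    samples, e.g. hydrogen-peroxide scavenging measured on 11 of 16).
    """

    composition: pd.DataFrame
    zscales: pd.DataFrame
    activities: dict[str, pd.Series] = field(default_factory=dict)
    reference_groups: pd.DataFrame | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        for name, act in self.activities.items():
            stray = act.index.difference(self.composition.index)
            if len(stray):
                raise TableValidationError(
                    f"activity {name!r} has sample id(s) not in the "
                    f"composition table: {stray.tolist()}"
                )

    def with_activities(self, activities: dict[str, pd.Series]) -> "Dataset":
        merged = {**self.activities, **activities}
        return dataclasses.replace(self, activities=merged)


def _data_path(name: str):
    return resources.files("hydrosar.data").joinpath(name)


def bundled_dataset() -> Dataset:
    """The bundled hempseed/pea protein-hydrolysate panel: 16 samples × 18
    amino acids (percent), the five published physicochemical group sums as
    a reference block, and the Hellberg 3-z scale table.

    Activities are not bundled (the published assay values live in the
    article's supplementary data); attach them with
    :func:`load_sd1_activities` / :meth:`Dataset.with_activities`.
    """
    with resources.as_file(_data_path("composition_hydrolysates.csv")) as p:
        comp = load_composition_table(p)
    with resources.as_file(_data_path("group_sums_reference.csv")) as p:
        ref = _read_delimited(p).astype(float)
    ref = ref.rename(columns={"ACAA": "AcAA"})  # canonical group capitalisation
    with resources.as_file(_data_path("hellberg_zscales.csv")) as p:
        z = load_zscale_table(p)
    return Dataset(
        composition=comp,
        zscales=z,
        reference_groups=ref,
        notes="16 hempseed/pea hydrolysate fractions; activities not bundled",
    )


def load_sd1_activities(source: str | Path | IO[str], sep: str = ",") -> dict[str, pd.Series]:
    """Loader hook for users who have the supplementary activity data.

    Expected layout: sample id in the first column, then one column per
    assay named ``dpph``, ``frap``, ``h2o2``, ``superoxide`` (case
    insensitive; missing cells allowed — the hydrogen-peroxide assay covers
    a subset of samples). Returns one Series per present assay.
    """
    df = _read_delimited(source, sep=sep)
    out: dict[str, pd.Series] = {}
    for name in ACTIVITY_UNITS:
        cols = {c.lower(): c for c in df.columns}
        if name in cols:
            s = df[cols[name]].dropna().astype(float)
            s.name = name
            s.attrs["units"] = ACTIVITY_UNITS[name]
            out[name] = s
    if not out:
        raise TableFormatError(
            f"no recognised activity columns ({', '.join(ACTIVITY_UNITS)}) "
            f"in {list(df.columns)}"
        )
    return out


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(i): _to_jsonable(r) for i, r in obj.iterrows()}
    return obj


def write_report(report, destination: str | Path, fmt: str = "json") -> Path:
    """Serialize a report dataclass (or dict of them) to ``destination``.

    ``json`` keeps full float precision (round-trips bit-equal through
    :func:`read_report`); ``csv`` renders a flat human-readable table.
    """
    payload = _to_jsonable(report)
    if payload in (None, {}, []):
        raise ValueError("refusing to write an empty report")
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        destination.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "csv":
        flat = payload if isinstance(payload, list) else [payload]
        pd.json_normalize(flat).to_csv(destination, index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return destination


def read_report(source: str | Path) -> dict | list:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(source).read_text())
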