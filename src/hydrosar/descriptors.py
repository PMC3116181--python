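"""Descriptor (X-matrix) construction for composition-activity modeling.

Three descriptor sets are supported, alone or combined:

``AA``
    the 18 raw amino-acid percentages;
``gAA``
    five physicochemical group sums — sulfur-containing (SCAA), positively
    charged (PCAA), hydrophobic (HAA), acidic (AcAA) and aromatic (AAA);
``z``
    the three Hellberg z-scale sums Σz_i = Σ_X z_i(X)·c_X over the 18
    amino acids, with c_X the percent composition (so Σz has units of
    z-score·percent).

Column order is fixed — AA in canonical label order, then the five groups,
then Σz1, Σz2, Σz3 — so coefficient and importance indices are stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import AA_LABELS, Dataset, TableValidationError, validate_composition

#: Physicochemical amino-acid groups, in the fixed output column order.
GROUPS: dict[str, tuple[str, ...]] = {
    "SCAA": ("CYS", "MET"),
    "PCAA": ("ARG", "LYS", "HIS"),
    "HAA": ("PRO", "ALA", "CYS", "VAL", "MET", "ILE", "LEU", "TYR", "PHE", "TRP"),
    "AcAA": ("ASX", "GLX"),
    "AAA": ("PHE", "TYR", "TRP"),
}

Z_COLUMNS = ("SUM_Z1", "SUM_Z2", "SUM_Z3")

#: Valid descriptor-set tokens; "all" is the 26-column combination.
X_SETS = ("AA", "gAA", "z", "all")

_SET_ALIASES = {
    "aa": "AA", "gaa": "gAA", "z": "z", "zscale": "z",
    "all": "all", "aa+gaa+z": "all", "combined": "all",
}


def resolve_x_set(token: str) -> str:
    try:
        return _SET_ALIASES[token.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown descriptor set {token!r}; expected one of {X_SETS}"
        ) from None


def group_sums(composition: pd.DataFrame) -> pd.DataFrame:
    """Per-sample physicochemical group sums (percent), one column per
    group in :data:`GROUPS` order."""
    validate_composition(composition)
    out = {g: composition[list(members)].sum(axis=1) for g, members in GROUPS.items()}
    return pd.DataFrame(out, index=composition.index)


def zscale_sums(composition: pd.DataFrame, zscales: pd.DataFrame) -> pd.DataFrame:
    """Composition-weighted z-scale sums Σz_i per sample.

    Linear in the composition: each column is the dot product of the
    18-vector of percentages with the corresponding z-score column.
    """
    validate_composition(composition)
    missing = [a for a in AA_LABELS if a not in zscales.index]
    if missing:
        raise TableValidationError(
            f"z-scale table missing label(s): {', '.join(missing)}"
        )
    z = zscales.loc[list(AA_LABELS), ["z1", "z2", "z3"]].to_numpy()
    c = composition[list(AA_LABELS)].to_numpy()
    return pd.DataFrame(c @ z, index=composition.index, columns=list(Z_COLUMNS))


def assemble_x(dataset: Dataset, x_set: str = "all") -> pd.DataFrame:
    """Build the X block for one descriptor set.

    Returns 18 (AA), 5 (gAA), 3 (z) or 26 (all) columns; the per-column
    set tag lives in ``result.attrs["set_tags"]``.
    """
    x_set = resolve_x_set(x_set)
    blocks: list[pd.DataFrame] = []
    tags: list[str] = []
    if x_set in ("AA", "all"):
        aa = dataset.composition[list(AA_LABELS)].copy()
        blocks.append(aa)
        tags += ["AA"] * len(AA_LABELS)
    if x_set in ("gAA", "all"):
        g = group_sums(dataset.composition)
        blocks.append(g)
        tags += ["gAA"] * g.shape[1]
    if x_set in ("z", "all"):
        z = zscale_sums(dataset.composition, dataset.zscales)
        blocks.append(z)
        tags += ["z"] * z.shape[1]
    x = pd.concat(blocks, axis=1)
    x.attrs["set_tags"] = tuple(tags)
    x.attrs["x_set"] = x_set
    return x


@dataclass
class ScalingParams:
    """Per-column centers and scales of a unit-variance autoscaling, plus
    the response's center/scale, kept for back-transformation."""

    x_columns: tuple[str, ...]
    x_center: np.ndarray
    x_scale: np.ndarray
    y_name: str
    y_center: float
    y_scale: float


def autoscale(
    x: pd.DataFrame, y: pd.Series
) -> tuple[pd.DataFrame, pd.Series, ScalingParams]:
    """Center every descriptor column and the response to mean zero and
    scale to unit sample standard deviation (n−1 denominator), so all
    variables contribute equally to the latent projection.

    Raises on any constant column (nothing to scale, and silently dropping
    would break the fixed-width column bookkeeping) and on non-overlapping
    or too-small sample sets.
    """
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError(f"need at least 3 common samples, have {len(common)}")
    x = x.loc[common]
    y = y.loc[common].astype(float)
    sd = x.std(axis=0, ddof=1)
    const = sd.index[sd <= 0].tolist()
    if const:
        raise ValueError(f"constant column(s) cannot be autoscaled: {', '.join(const)}")
    y_sd = float(y.std(ddof=1))
    if y_sd <= 0:
        raise ValueError("response has zero variance")
    params = ScalingParams(
        x_columns=tuple(x.columns),
        x_center=x.mean(axis=0).to_numpy(),
        x_scale=sd.to_numpy(),
        y_name=str(y.name),
        y_center=float(y.mean()),
        y_scale=y_sd,
    )
    xs = (x - params.x_center) / params.x_scale
    ys = (y - params.y_center) / params.y_scale
    return xs, ys, params


def unscale_y(ys, params: ScalingParams):
    """Invert the response autoscaling."""
    return ys * params.y_scale + params.y_center


def unscale_x(xs: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Invert the descriptor autoscaling."""
    return xs * params.x_scale + params.x_center


class DescriptorBuilder(BaseEstimator, TransformerMixin):
    """Transformer turning an 18-column percent-composition frame into a
    descriptor block (``x_set`` ∈ {"AA", "gAA", "z", "all"}).

    Stateless apart from validation; the z-scale table defaults to the
    bundled Hellberg scores at transform time.
    """

    def __init__(self, x_set: str = "all", zscales: pd.DataFrame | None = None):
        self.x_set = x_set
        self.zscales = zscales

    def fit(self, X: pd.DataFrame, y=None) -> "DescriptorBuilder":
        validate_composition(X)
        resolve_x_set(self.x_set)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from .data_io import bundled_dataset

        z = self.zscales if self.zscales is not None else bundled_dataset().zscales
        return assemble_x(Dataset(composition=X, zscales=z), self.x_set)

    def get_feature_names_out(self, input_features=None):
        names: list[str] = []
        x_set = resolve_x_set(self.x_set)
        if x_set in ("AA", "all"):
            names += list(AA_LABELS)
        if x_set in ("gAA", "all"):
            names += list(GROUPS)
        if x_set in ("z", "all"):
            names += list(Z_COLUMNS)
        return np.asarray(names, dtype=object)
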