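"""Synthetic hydrolysate-like datasets with known ground truth.

Compositions are drawn from a Dirichlet distribution (scaled to 100%), so
every simulated sample respects the closed-sum constraint real amino-acid
analyses obey — including the collinearity that constraint induces among
composition columns, which is deliberately preserved. Default
concentration weights are proportional to the bundled panel's mean
composition with a total concentration of 12, giving per-residue spreads
that bracket the observed ranges of the real panel (e.g. ARG roughly
1–30%, CYS 0.1–1.6%).

Activities are noisy linear functions of chosen descriptors with known
coefficients. Descriptor values flow through the production descriptor
code (never a duplicate formula), so planted truths exercise the real
pipeline. Noise can be stated directly (``noise_sd``) or via the planted
coefficient of determination (``target_r2``), from which the noise
standard deviation is solved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .data_io import AA_LABELS, Dataset, bundled_dataset
from .descriptors import assemble_x

#: Total Dirichlet concentration of the default composition sampler: the
#: largest value whose n=1000 per-residue ranges still bracket the real
#: panel's extrema (larger totals under-disperse; smaller ones make the
#: scarce residues far spikier than any real hydrolysate panel).
DEFAULT_TOTAL_CONCENTRATION = 30.0


@lru_cache(maxsize=1)
def default_concentration() -> pd.Series:
    """Dirichlet weights proportional to the bundled panel's mean
    composition."""
    mean_frac = bundled_dataset().composition.mean() / 100.0
    return (DEFAULT_TOTAL_CONCENTRATION * mean_frac).rename("concentration")


def generate_compositions(
    n: int,
    seed: int,
    concentration: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw ``n`` amino-acid composition rows summing to exactly 100%."""
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if concentration is None:
        alpha = default_concentration().to_numpy()
    else:
        if isinstance(concentration, pd.Series):
            concentration = concentration.reindex(list(AA_LABELS)).to_numpy()
        alpha = np.asarray(concentration, dtype=float)
    if alpha.shape != (len(AA_LABELS),):
        raise ValueError(f"need {len(AA_LABELS)} concentration weights")
    if np.any(~np.isfinite(alpha)) or np.any(alpha <= 0):
        raise ValueError("concentration weights must be positive and finite")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(alpha, size=n)
    return pd.DataFrame(
        props * 100.0,
        index=[f"S{i + 1}" for i in range(n)],
        columns=list(AA_LABELS),
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic activity.

    ``coefficients`` map descriptor labels (amino acids, group names, or
    SUM_Z1..3) to the activity change per percent composition (per
    z-score·percent for the Σz descriptors). Exactly one of ``noise_sd``
    (activity units) or ``target_r2`` (fraction of activity variance the
    signal should carry) sets the noise level; both ``None`` means
    noiseless.
    """

    coefficients: dict[str, float]
    seed: int = 0
    noise_sd: float | None = None
    target_r2: float | None = None
    intercept: float = 0.0

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(self.coefficients),
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "target_r2": self.target_r2,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)


def generate_activity(
    composition: pd.DataFrame,
    zscales: pd.DataFrame,
    truth: SyntheticTruth,
    name: str = "synthetic",
) -> pd.Series:
    """Simulate y = intercept + Σ β_d·descriptor_d + ε for the planted
    truth, with descriptors computed by the production descriptor code."""
    if truth.noise_sd is not None and truth.target_r2 is not None:
        raise ValueError("give noise_sd or target_r2, not both")
    x = assemble_x(Dataset(composition=composition, zscales=zscales), "all")
    unknown = sorted(set(truth.coefficients) - set(x.columns))
    if unknown:
        raise KeyError(f"unknown descriptor label(s): {', '.join(unknown)}")
    signal = truth.intercept + sum(
        beta * x[label] for label, beta in truth.coefficients.items()
    )
    signal = pd.Series(signal, index=composition.index, dtype=float)

    if truth.noise_sd is not None:
        sd = float(truth.noise_sd)
    elif truth.target_r2 is not None:
        r2 = float(truth.target_r2)
        if not 0 < r2 <= 1:
            raise ValueError(f"target_r2 must be in (0, 1], got {r2}")
        # var(noise) solves signal_var / (signal_var + sd²) = target R²
        sd = float(signal.std(ddof=1)) * np.sqrt((1.0 - r2) / r2)
    else:
        sd = 0.0
    rng = np.random.default_rng(truth.seed)
    y = signal + rng.normal(0.0, sd, size=len(signal)) if sd > 0 else signal
    y.name = name
    y.attrs["units"] = "synthetic"
    return y


@dataclass
class BenchmarkConfig:
    """Shape of the default benchmark: a panel like the bundled one (16
    samples, four activities, one assay covering only 11 samples) with
    planted signal at R² ≈ 0.7."""

    n: int = 16
    seed: int = 0
    target_r2: float = 0.7
    subset_activity: str = "h2o2"
    subset_n: int = 11
    truths: dict[str, dict[str, float]] = field(default_factory=lambda: {
        # signs echo the qualitative composition-activity relations the
        # package is designed to detect
        "dpph": {"HAA": 0.6, "PCAA": -0.7},
        "frap": {"SCAA": 3.0, "PCAA": -0.6},
        "h2o2": {"AcAA": 0.8, "PCAA": -0.5},
        "superoxide": {"LYS": 1.0, "LEU": 0.8, "SCAA": -4.0},
    })


def make_benchmark(
    config: BenchmarkConfig | None = None,
) -> tuple[Dataset, dict[str, SyntheticTruth]]:
    """Generate a full synthetic benchmark dataset plus its truths.

    Deterministic under ``config.seed``; per-activity noise seeds are
    derived from it. The subset activity keeps only the first
    ``subset_n`` samples, mimicking an assay run on part of the panel.
    """
    cfg = config or BenchmarkConfig()
    zscales = bundled_dataset().zscales
    comp = generate_compositions(cfg.n, seed=cfg.seed)
    truths: dict[str, SyntheticTruth] = {}
    activities: dict[str, pd.Series] = {}
    for k, (name, coefs) in enumerate(sorted(cfg.truths.items())):
        truth = SyntheticTruth(
            coefficients=dict(coefs),
            seed=cfg.seed * 1009 + k + 1,
            target_r2=cfg.target_r2,
        )
        y = generate_activity(comp, zscales, truth, name=name)
        if name == cfg.subset_activity:
            y = y.iloc[: cfg.subset_n]
        truths[name] = truth
        activities[name] = y
    dataset = Dataset(
        composition=comp,
        zscales=zscales,
        activities=activities,
        notes=f"synthetic benchmark (seed={cfg.seed}, planted R2={cfg.target_r2})",
    )
    return dataset, truths
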