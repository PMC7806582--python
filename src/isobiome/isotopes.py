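"""Two-endmember stable-isotope mixing model for seabird diet metrics.

Converts consumer blood δ13C/δ15N into the two diet covariates used
throughout the analysis — the proportional use of littoral carbon (alpha)
and trophic position — plus δ34S passed through unchanged.

The model is the classical two-source formulation: alpha places the
consumer's (optionally trophic-discrimination-corrected) δ13C on the mixing
line between a pelagic (alpha = 0) and a littoral (alpha = 1) baseline, and
trophic position is the baseline trophic level plus the consumer's δ15N
enrichment over the alpha-weighted baseline divided by the per-level
enrichment factor:

    alpha = (δ13C_c − Δ13C·tc − δ13C_pel) / (δ13C_lit − δ13C_pel)
    TP    = λ + (δ15N_c − [alpha·δ15N_lit + (1 − alpha)·δ15N_pel]) / Δ15N

alpha is deliberately *not* clipped to [0, 1]: clipping would distort the
GLM covariates.  Values outside a generous [−0.25, 1.25] band are flagged
in the log instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .io import logger

ALPHA_FLAG_RANGE = (-0.25, 1.25)


@dataclass
class MixingModelConfig:
    """Baselines and discrimination constants of the mixing model.

    Defaults for the enrichment constants follow the standard convention:
    Δ15N = 3.4 permil per trophic level, Δ13C = 0.4 permil per level
    (applied ``trophic_correction`` times, default 0), baseline trophic
    level λ = 2 (primary consumers).  Baseline prey values have no universal
    default and must be supplied.
    """

    d13c_littoral: float
    d13c_pelagic: float
    d15n_littoral: float
    d15n_pelagic: float
    delta15n_per_level: float = 3.4
    delta13c_per_level: float = 0.4
    lambda_baseline: float = 2.0
    trophic_correction: float = 0.0

    def __post_init__(self):
        if self.d13c_littoral == self.d13c_pelagic:
            raise ValueError("littoral and pelagic d13C baselines must differ")
        if self.delta15n_per_level <= 0:
            raise ValueError("delta15n_per_level must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "MixingModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def littoral_carbon_proportion(d13c_consumer, cfg: MixingModelConfig):
    """Mixing fraction alpha of littoral carbon from consumer δ13C."""
    corrected = (
        np.asarray(d13c_consumer, dtype=float)
        - cfg.delta13c_per_level * cfg.trophic_correction
    )
    alpha = (corrected - cfg.d13c_pelagic) / (cfg.d13c_littoral - cfg.d13c_pelagic)
    return alpha if alpha.ndim else float(alpha)


def trophic_position(d15n_consumer, alpha, cfg: MixingModelConfig):
    """Trophic position from consumer δ15N and the alpha-weighted baseline."""
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be finite")
    base = alpha * cfg.d15n_littoral + (1.0 - alpha) * cfg.d15n_pelagic
    tp = cfg.lambda_baseline + (np.asarray(d15n_consumer, dtype=float) - base) / cfg.delta15n_per_level
    return tp if tp.ndim else float(tp)


def invert_mixing_model(alpha, tp, cfg: MixingModelConfig):
    """The unique (δ13C, δ15N) that the forward model maps to (alpha, TP)."""
    alpha = np.asarray(alpha, dtype=float)
    tp = np.asarray(tp, dtype=float)
    d13c = (
        cfg.d13c_pelagic
        + alpha * (cfg.d13c_littoral - cfg.d13c_pelagic)
        + cfg.delta13c_per_level * cfg.trophic_correction
    )
    base = alpha * cfg.d15n_littoral + (1.0 - alpha) * cfg.d15n_pelagic
    d15n = base + (tp - cfg.lambda_baseline) * cfg.delta15n_per_level
    if d13c.ndim:
        return d13c, d15n
    return float(d13c), float(d15n)


def compute_diet_metrics(isotopes: pd.DataFrame, cfg: MixingModelConfig) -> pd.DataFrame:
    """Per-bird diet metrics (alpha, trophic_position, d34s) from isotopes.

    Rows with any missing isotope are skipped with a warning.  Alphas
    outside [-0.25, 1.25] are flagged (never clipped).
    """
    ok = isotopes[["d13c", "d15n", "d34s"]].notna().all(axis=1)
    skipped = isotopes.index[~ok].tolist()
    if skipped:
        logger.warning("skipping %d birds with missing isotopes: %s", len(skipped), skipped)
    iso = isotopes.loc[ok]
    alpha = littoral_carbon_proportion(iso["d13c"].to_numpy(), cfg)
    tp = trophic_position(iso["d15n"].to_numpy(), alpha, cfg)
    out = pd.DataFrame(
        {"alpha": alpha, "trophic_position": tp, "d34s": iso["d34s"].to_numpy()},
        index=iso.index,
    )
    lo, hi = ALPHA_FLAG_RANGE
    odd = out.index[(out["alpha"] < lo) | (out["alpha"] > hi)].tolist()
    if odd:
        logger.warning("alpha outside [%s, %s] for birds %s (not clipped)", lo, hi, odd)
    return out
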