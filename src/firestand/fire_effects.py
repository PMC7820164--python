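"""Fire effects: crown consumption -> tree mortality, plus a surrogate burner.

Mortality follows the logistic form used operationally for fire-caused tree
death, with percent crown consumption substituted for percent crown volume
scorched:

    p = logistic(b0 + b1*C + b2*C^2 + b3*dbh + b4*C*dbh),   C = 100*fraction

with species-specific coefficients.  A tree is designated fire-killed when
p >= 0.5 (threshold configurable).  The coefficient table shipped here is
ILLUSTRATIVE ONLY — shaped to the usual qualitative structure (probability
rising in consumption, falling in diameter, thick-barked pines more
resistant than firs) — and is NOT a published regression; supply your own
table for real analyses.

The surrogate consumption generator stands in for a physics-based fire
simulation.  Its mechanism mirrors the fire-ecology narrative: crown
consumption rises with neighborhood basal area (dense clumps sustain crown
fire; less convective cooling) and falls with crown base height (high
crowns resist ignition from surface fire):

    consumption_i = logistic(a0 + a1*z(NBA_i) - a2*z(CBH_i) + eps_i)

where NBA_i is the basal area (m^2) of neighbors within ``radius`` meters,
z(.) standardizes either within the map (default) or against fixed
reference scales (so that denser stands receive more consumption on
average — the cross-stand mechanism), and eps is Gaussian logit noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit

from .stem_data import STATUS_ALIVE, STATUS_KILLED, StemMap, ValidationError

__all__ = [
    "MortalityCoefficients",
    "SurrogateFireConfig",
    "mortality_probability",
    "classify_mortality",
    "surrogate_consumption",
    "illustrative_coefficients",
]

COEF_NAMES = ("b0", "b1", "b2", "b3", "b4")
DEFAULT_SPECIES = "__default__"


@dataclass
class MortalityCoefficients:
    """Species-keyed logistic coefficients; consumption scale is percent.

    ``rows[species] = (b0, b1, b2, b3, b4)`` for
    logit p = b0 + b1*C + b2*C^2 + b3*dbh + b4*C*dbh with C in [0, 100]
    and dbh in cm.  A row keyed ``__default__`` covers unlisted species.
    """

    rows: dict[str, tuple[float, float, float, float, float]]

    def for_species(self, species: str) -> tuple[float, ...]:
        if species in self.rows:
            return self.rows[species]
        if DEFAULT_SPECIES in self.rows:
            return self.rows[DEFAULT_SPECIES]
        raise KeyError(
            f"no mortality coefficients for species {species!r} and no default row"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityCoefficients":
        """Read a delimited table with columns species, b0..b4."""
        df = pd.read_csv(path)
        missing = {"species", *COEF_NAMES} - set(df.columns)
        if missing:
            raise ValueError(f"coefficient table missing columns {sorted(missing)}")
        rows = {
            str(row["species"]): tuple(float(row[c]) for c in COEF_NAMES)
            for _, row in df.iterrows()
        }
        return cls(rows)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"species": sp, **dict(zip(COEF_NAMES, co))} for sp, co in self.rows.items()]
        ).to_csv(path, index=False)


def illustrative_coefficients() -> MortalityCoefficients:
    """Synthetic, non-authoritative coefficient table for demonstrations.

    Structure only: mortality odds rise with percent crown consumption and
    fall with stem diameter; firs die easier than thick-barked pines.
    """
    return MortalityCoefficients(
        {
            "ABCO": (-4.6, 0.10, 0.0, -0.040, 0.0),   # white fir: fire-sensitive
            "CADE": (-5.0, 0.10, 0.0, -0.045, 0.0),   # incense-cedar
            "PIPO": (-6.0, 0.10, 0.0, -0.055, 0.0),   # ponderosa: resistant
            "PIJE": (-6.0, 0.10, 0.0, -0.055, 0.0),   # Jeffrey pine
            "PILA": (-5.5, 0.10, 0.0, -0.050, 0.0),   # sugar pine
            DEFAULT_SPECIES: (-5.5, 0.10, 0.0, -0.045, 0.0),
        }
    )


def mortality_probability(
    dbh: float | np.ndarray,
    species: str | np.ndarray,
    consumption: float | np.ndarray,
    coeffs: MortalityCoefficients,
) -> np.ndarray:
    """Per-tree death probability from the species logistic equations.

    ``consumption`` is a fraction in [0, 1]; internally rescaled to percent.
    """
    dbh = np.atleast_1d(np.asarray(dbh, dtype=float))
    consumption = np.atleast_1d(np.asarray(consumption, dtype=float))
    if np.any((consumption < 0) | (consumption > 1)):
        raise ValueError("consumption fractions must lie in [0, 1]")
    species = np.atleast_1d(np.asarray(species, dtype=object))
    if len(species) == 1:
        species = np.repeat(species, len(dbh))
    C = 100.0 * consumption
    coef = np.array([coeffs.for_species(sp) for sp in species], dtype=float)
    logit = (
        coef[:, 0]
        + coef[:, 1] * C
        + coef[:, 2] * C**2
        + coef[:, 3] * dbh
        + coef[:, 4] * C * dbh
    )
    return expit(logit)


def classify_mortality(
    stem_map: StemMap,
    coeffs: MortalityCoefficients,
    threshold: float = 0.5,
) -> StemMap:
    """Label every tree alive/killed by thresholding its death probability.

    Deterministic (no coin flip): status = killed iff p >= threshold, the
    >=50%-likelihood designation rule.  Requires a consumption fraction on
    every tree.
    """
    df = stem_map.trees
    if "crown_consumption" not in df.columns or df["crown_consumption"].isna().any():
        missing = (
            df.loc[df["crown_consumption"].isna(), "id"].tolist()
            if "crown_consumption" in df.columns
            else df["id"].tolist()
        )
        raise ValidationError(f"missing crown consumption for ids {missing[:5]}")
    p = mortality_probability(
        df["dbh"].to_numpy(float),
        df["species"].to_numpy(object),
        df["crown_consumption"].to_numpy(float),
        coeffs,
    )
    status = np.where(p >= threshold, STATUS_KILLED, STATUS_ALIVE)
    return stem_map.with_columns(mortality_prob=p, status=status)


# ---------------------------------------------------------------------------
# surrogate fire


@dataclass
class SurrogateFireConfig:
    """Neighborhood-driven crown-consumption surrogate.

    radius
        neighborhood radius in m; default 6 m, the tree-group linkage scale.
    a0
        baseline logit; logistic(a0) is the consumption of a tree with
        reference-average neighborhood and crown base (noise off).
    a1, a2
        non-negative gains on standardized neighborhood basal area and on
        the standardized crown-base-height deficit.
    noise_sd
        Gaussian sd on the logit.
    nba_ref, cbh_ref
        optional fixed (mean, sd) reference scales for the standardization;
        ``None`` standardizes within the map.  Fixed references let mean
        consumption grow with absolute stand density across stands.
    use_cbh
        set False to drop the crown-base term (maps without crown data).
    """

    radius: float = 6.0
    a0: float = -1.0
    a1: float = 2.0
    a2: float = 1.0
    noise_sd: float = 0.3
    nba_ref: tuple[float, float] | None = None
    cbh_ref: tuple[float, float] | None = None
    use_cbh: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("a1 and a2 must be non-negative")


def neighborhood_basal_area(stem_map: StemMap, radius: float) -> np.ndarray:
    """Per-tree basal area (m^2) of neighbors within ``radius`` m, self excluded."""
    coords = stem_map.coords
    ba = np.pi * (stem_map.marks("dbh") / 200.0) ** 2
    d = cdist(coords, coords)
    near = (d <= radius) & (d > 0)
    return near @ ba


def _standardize(x: np.ndarray, ref: tuple[float, float] | None) -> np.ndarray:
    if ref is None:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    mean, sd = ref
    return (x - mean) / sd


def surrogate_consumption(
    stem_map: StemMap, config: SurrogateFireConfig
) -> StemMap:
    """Attach surrogate per-tree crown-consumption fractions to the map."""
    win = stem_map.window
    if config.radius > min(win.width, win.height):
        warnings.warn(
            "neighborhood radius exceeds the window's shorter side; "
            "edge bias will be severe",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    nba = neighborhood_basal_area(stem_map, config.radius)
    logit = config.a0 + config.a1 * _standardize(nba, config.nba_ref)
    if config.use_cbh:
        if "crown_base_height" not in stem_map.trees.columns:
            raise ValidationError(
                "crown_base_height required; set use_cbh=False to ignore it"
            )
        cbh = stem_map.trees["crown_base_height"].to_numpy(float)
        logit = logit - config.a2 * _standardize(cbh, config.cbh_ref)
    if config.noise_sd > 0:
        logit = logit + rng.normal(0.0, config.noise_sd, size=stem_map.n)
    consumption = np.clip(expit(logit), 0.0, 1.0)
    return stem_map.with_columns(crown_consumption=consumption)
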