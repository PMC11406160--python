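"""Consumer and resource communities: synthetic generation and table I/O.

The synthetic generator emulates the structure of the data the analysis
needs: a handful of consumer colonies (default three, mirroring replicate
colonies of a single leaf-cutter ant species) whose body masses vary
log-normally around a median and share one bite-force allometry, and a
plant community whose required leaf-cutting forces are log-normally
distributed (strictly positive, right-skewed) so that they span the
consumers' bite-force range.  Tables round-trip through CSV/TSV with
unit-bearing column names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biomech import AllometricModel, scale_trait

__all__ = [
    "SyntheticConfig",
    "Consumer",
    "Resource",
    "SchemaError",
    "generate_community",
    "load_community",
    "write_community",
    "consumers_to_frame",
    "resources_to_frame",
]

CONSUMER_REQUIRED_COLUMNS = ("id", "reference_mass_mg")
RESOURCE_REQUIRED_COLUMNS = ("id", "cutting_force_mn")


class SchemaError(ValueError):
    """A trait table is missing required columns or contains invalid rows."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic community generator.

    Medians are on the natural scale; sigmas are standard deviations of the
    log.  Defaults describe a small leaf-cutter-ant-like system: three
    colonies of ~10 mg workers whose bite forces (``10 * m**(2/3)`` mN)
    fall inside a plant community whose cutting forces have median 40 mN,
    and a 2% body-mass loss per degree C of warming.
    """

    n_consumers: int = 3
    n_resources: int = 100
    consumer_mass_median: float = 10.0
    consumer_mass_sigma: float = 0.3
    allometry_prefactor: float = 10.0
    allometry_exponent: float = 2.0 / 3.0
    cutting_force_median: float = 40.0
    cutting_force_sigma: float = 0.6
    alpha: float = 0.98
    reference_temperature: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` listing every invalid field."""
        problems = []
        if not (isinstance(self.n_consumers, (int, np.integer)) and self.n_consumers >= 1):
            problems.append(f"n_consumers must be an integer >= 1, got {self.n_consumers!r}")
        if not (isinstance(self.n_resources, (int, np.integer)) and self.n_resources >= 1):
            problems.append(f"n_resources must be an integer >= 1, got {self.n_resources!r}")
        for name in ("consumer_mass_median", "allometry_prefactor",
                     "cutting_force_median", "alpha"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                problems.append(f"{name} must be positive and finite, got {value!r}")
        for name in ("consumer_mass_sigma", "cutting_force_sigma"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value >= 0):
                problems.append(f"{name} must be >= 0 and finite, got {value!r}")
        if not math.isfinite(self.allometry_exponent):
            problems.append(f"allometry_exponent must be finite, got {self.allometry_exponent!r}")
        if not math.isfinite(self.reference_temperature):
            problems.append(
                f"reference_temperature must be finite, got {self.reference_temperature!r}"
            )
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    def allometry(self) -> AllometricModel:
        return AllometricModel(self.allometry_prefactor, self.allometry_exponent)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SyntheticConfig fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class Consumer:
    """A consumer node (e.g. an ant colony) with its bite-force allometry."""

    id: str
    reference_mass: float  # mg, at the reference temperature
    allometry: AllometricModel
    baseline_bite_force: float = field(default=float("nan"))  # mN, cached

    def __post_init__(self) -> None:
        if not self.reference_mass > 0:
            raise ValueError(
                f"consumer {self.id!r}: reference_mass must be positive, "
                f"got {self.reference_mass!r}"
            )
        if math.isnan(self.baseline_bite_force):
            object.__setattr__(
                self, "baseline_bite_force", scale_trait(self.reference_mass, self.allometry)
            )


@dataclass(frozen=True)
class Resource:
    """A resource node (e.g. a plant) requiring a cutting force to be consumed."""

    id: str
    cutting_force: float  # mN required to cut/penetrate
    abundance: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.cutting_force > 0:
            raise ValueError(
                f"resource {self.id!r}: cutting_force must be positive, "
                f"got {self.cutting_force!r}"
            )
        if self.abundance is not None and not self.abundance >= 0:
            raise ValueError(
                f"resource {self.id!r}: abundance must be >= 0, got {self.abundance!r}"
            )


def generate_community(
    config: SyntheticConfig,
) -> tuple[list[Consumer], list[Resource]]:
    """Draw a consumer/resource community from the configured log-normals.

    Masses and cutting forces are ``median * exp(sigma * Z)`` with standard
    normal ``Z``, so the configured medians are the distribution medians
    exactly.  Deterministic for a fixed (seed, config) pair.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    allometry = config.allometry()

    masses = config.consumer_mass_median * np.exp(
        config.consumer_mass_sigma * rng.standard_normal(config.n_consumers)
    )
    cuts = config.cutting_force_median * np.exp(
        config.cutting_force_sigma * rng.standard_normal(config.n_resources)
    )

    width_c = len(str(config.n_consumers))
    width_r = len(str(config.n_resources))
    consumers = [
        Consumer(id=f"colony_{i + 1:0{width_c}d}", reference_mass=float(m), allometry=allometry)
        for i, m in enumerate(masses)
    ]
    resources = [
        Resource(id=f"plant_{j + 1:0{width_r}d}", cutting_force=float(c))
        for j, c in enumerate(cuts)
    ]
    return consumers, resources


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def consumers_to_frame(consumers: Sequence[Consumer]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in consumers],
            "reference_mass_mg": [c.reference_mass for c in consumers],
            "prefactor": [c.allometry.prefactor for c in consumers],
            "exponent": [c.allometry.exponent for c in consumers],
        }
    )


def resources_to_frame(resources: Sequence[Resource]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "id": [r.id for r in resources],
            "cutting_force_mn": [r.cutting_force for r in resources],
        }
    )
    if any(r.abundance is not None for r in resources):
        frame["abundance"] = [r.abundance for r in resources]
    return frame


def write_community(
    consumers: Sequence[Consumer],
    resources: Sequence[Resource],
    consumer_path: str | Path,
    resource_path: str | Path,
) -> None:
    """Write trait tables as CSV or TSV (chosen from the file extension)."""
    consumer_path, resource_path = Path(consumer_path), Path(resource_path)
    consumers_to_frame(consumers).to_csv(
        consumer_path, sep=_sep_for(consumer_path), index=False
    )
    resources_to_frame(resources).to_csv(
        resource_path, sep=_sep_for(resource_path), index=False
    )


def _check_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{what} table is missing required column(s): {', '.join(missing)}"
        )


def _positive_float(value, row: int, column: str, what: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{what} table row {row}: column {column!r} is not numeric ({value!r})"
        ) from None
    if not math.isfinite(out) or out <= 0:
        raise SchemaError(
            f"{what} table row {row}: column {column!r} must be positive, got {value!r}"
        )
    return out


def load_community(
    consumer_table_path: str | Path,
    resource_table_path: str | Path,
    default_allometry: Optional[AllometricModel] = None,
) -> tuple[list[Consumer], list[Resource]]:
    """Load trait tables written by :func:`write_community` (or conforming).

    Consumer tables need ``id`` and ``reference_mass_mg``; per-row
    ``prefactor``/``exponent`` columns override ``default_allometry``.
    Resource tables need ``id`` and ``cutting_force_mn`` with an optional
    ``abundance``.  Row order is preserved.
    """
    consumer_path, resource_path = Path(consumer_table_path), Path(resource_table_path)
    cframe = pd.read_csv(consumer_path, sep=_sep_for(consumer_path))
    rframe = pd.read_csv(resource_path, sep=_sep_for(resource_path))
    _check_columns(cframe, CONSUMER_REQUIRED_COLUMNS, "consumer")
    _check_columns(rframe, RESOURCE_REQUIRED_COLUMNS, "resource")

    has_allometry_cols = "prefactor" in cframe.columns and "exponent" in cframe.columns
    if not has_allometry_cols and default_allometry is None:
        raise SchemaError(
            "consumer table has no prefactor/exponent columns and no "
            "default allometry was supplied"
        )

    consumers = []
    for i, row in enumerate(cframe.itertuples(index=False)):
        mass = _positive_float(row.reference_mass_mg, i, "reference_mass_mg", "consumer")
        if has_allometry_cols and not (
            pd.isna(row.prefactor) or pd.isna(row.exponent)
        ):
            allometry = AllometricModel(float(row.prefactor), float(row.exponent))
        else:
            allometry = default_allometry
            if allometry is None:
                raise SchemaError(
                    f"consumer table row {i}: missing allometry and no default supplied"
                )
        consumers.append(Consumer(id=str(row.id), reference_mass=mass, allometry=allometry))

    resources = []
    has_abundance = "abundance" in rframe.columns
    for i, row in enumerate(rframe.itertuples(index=False)):
        cut = _positive_float(row.cutting_force_mn, i, "cutting_force_mn", "resource")
        abundance = None
        if has_abundance and not pd.isna(row.abundance):
            abundance = float(row.abundance)
            if abundance < 0:
                raise SchemaError(
                    f"resource table row {i}: abundance must be >= 0, got {abundance!r}"
                )
        resources.append(Resource(id=str(row.id), cutting_force=cut, abundance=abundance))

    return consumers, resources
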