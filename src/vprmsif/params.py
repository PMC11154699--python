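"""Per-vegetation-class parameter tables and their CSV interfaces.

Holds the light-use-efficiency model parameters (λ, SWdown0, α, β) per
class and parameter set, the photosynthesis temperature limits, the
cross-sensor SIF scaling factors, the biome-specific SIF→GPP linear
coefficients, the GPP refinement scalars (η, ε) and the refined-respiration
coefficients (ν, τ, κ).  Packaged reference tables live under
``vprmsif/data`` and are loaded with :func:`packaged_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "ClassParams",
    "VPRMParams",
    "TemperatureLimits",
    "SIFScaling",
    "SIFGPPCoeffs",
    "RefineScalars",
    "RecoRefineParams",
    "packaged_table",
]

_PACKAGED = {
    "vprm_params": "vprm_params.csv",
    "sif_scaling": "sif_scaling.csv",
    "sif_gpp_coeffs": "sif_gpp_coeffs.csv",
    "gpp_refine_eta": "gpp_refine_eta.csv",
    "reco_refine_params": "reco_refine_params.csv",
}


def packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables as a DataFrame.

    ``name`` is one of ``vprm_params`` (per-class λ/SWdown0/α/β for the
    tropical and european sets), ``sif_scaling`` (cross-sensor factors S),
    ``sif_gpp_coeffs`` (γ, C per class and SIF product), ``gpp_refine_eta``
    (reference η per class and product) and ``reco_refine_params``
    (reference ν/τ/κ per class and experiment).
    """
    if name not in _PACKAGED:
        raise KeyError(f"unknown packaged table {name!r}; options: {sorted(_PACKAGED)}")
    ref = resources.files("vprmsif.data").joinpath(_PACKAGED[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass(frozen=True)
class ClassParams:
    """λ, SWdown0, α, β for one vegetation class.

    λ: light-use efficiency (µmol CO2 m⁻² s⁻¹ per µmol SWdown m⁻² s⁻¹);
    SWdown0: half-saturation radiation; α: respiration slope per °C;
    β: respiration intercept (µmol CO2 m⁻² s⁻¹).
    """

    lambda_: float
    swdown0: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.swdown0 <= 0:
            raise ValueError("swdown0 must be positive")


class VPRMParams:
    """Per-class model parameters for one parameter set (tropical/european)."""

    def __init__(self, table: pd.DataFrame, parameter_set: str = "tropical"):
        required = {"class", "set", "lambda", "swdown0", "alpha", "beta"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"parameter table missing columns {sorted(missing)}")
        sub = table[table["set"] == parameter_set]
        if sub.empty:
            raise ValueError(f"no rows for parameter set {parameter_set!r}")
        dup = sub["class"].duplicated()
        if dup.any():
            raise ValueError("duplicate class rows in parameter set")
        self.parameter_set = parameter_set
        self.table = table
        self._by_class = {
            row["class"]: ClassParams(
                row["lambda"], row["swdown0"], row["alpha"], row["beta"]
            )
            for _, row in sub.iterrows()
        }

    @classmethod
    def from_csv(cls, path, parameter_set: str = "tropical") -> "VPRMParams":
        return cls(pd.read_csv(path), parameter_set)

    @classmethod
    def packaged(cls, parameter_set: str = "tropical") -> "VPRMParams":
        return cls(packaged_table("vprm_params"), parameter_set)

    def __getitem__(self, cls_name: str) -> ClassParams:
        try:
            return self._by_class[cls_name]
        except KeyError:
            raise KeyError(
                f"no parameters for vegetation class {cls_name!r} in set "
                f"{self.parameter_set!r}"
            ) from None

    def __contains__(self, cls_name: str) -> bool:
        return cls_name in self._by_class

    def classes(self) -> list[str]:
        return list(self._by_class)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class TemperatureLimits:
    """Photosynthesis temperature limits and the respiration clamp, in °C.

    ``t_min``/``t_max`` bound photosynthetic activity (zero outside),
    ``t_opt`` is the optimum where the temperature scalar reaches 1, and
    ``t_thresh`` clamps air temperature from below in the respiration
    equation so winter respiration does not go negative.
    """

    t_min: float = 0.0
    t_opt: float = 20.0
    t_max: float = 45.0
    t_thresh: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("require t_min < t_opt < t_max")


def _per_class_frame(
    table: pd.DataFrame, required: set[str], kind: str
) -> pd.DataFrame:
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{kind} table missing columns {sorted(missing)}")
    if table["class"].duplicated().any():
        raise ValueError(f"duplicate class rows in {kind} table")
    return table.reset_index(drop=True)


class SIFScaling:
    """Per-class cross-sensor scaling factors S (TROPOSIF / GOSIF).

    ``table`` has columns ``class``, ``s`` (dimensionless factor, > 0),
    ``r2`` (squared Pearson correlation of the matched 8-day pairs) and
    ``n`` (pair count; NaN for externally supplied factors).
    """

    def __init__(self, table: pd.DataFrame):
        self.table = _per_class_frame(table, {"class", "s"}, "SIF scaling")
        if (self.table["s"] <= 0).any():
            raise ValueError("scaling factors must be positive")
        self._s = dict(zip(self.table["class"], self.table["s"]))

    @classmethod
    def from_csv(cls, path) -> "SIFScaling":
        return cls(pd.read_csv(path))

    @classmethod
    def packaged(cls) -> "SIFScaling":
        return cls(packaged_table("sif_scaling"))

    def factor(self, cls_name: str) -> float:
        try:
            return self._s[cls_name]
        except KeyError:
            raise KeyError(f"no scaling factor for class {cls_name!r}") from None

    def __contains__(self, cls_name: str) -> bool:
        return cls_name in self._s

    def classes(self) -> list[str]:
        return list(self._s)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class SIFGPPCoeffs:
    """Per-class linear SIF→GPP coefficients for one SIF product.

    GPP = γ·SIF + C with γ in (µmol m⁻² s⁻¹)/(mW m⁻² sr⁻¹ nm⁻¹) and C in
    µmol m⁻² s⁻¹.  ``product`` tags which SIF product (``gosif`` or
    ``troposif``) the coefficients apply to.
    """

    def __init__(self, table: pd.DataFrame, product: str):
        if product not in ("gosif", "troposif"):
            raise ValueError("product must be 'gosif' or 'troposif'")
        if "product" in table.columns:
            table = table[table["product"] == product].drop(columns="product")
        self.table = _per_class_frame(table, {"class", "gamma", "c"}, "SIF-GPP")
        if self.table.empty:
            raise ValueError(f"no coefficient rows for product {product!r}")
        if (self.table["gamma"] <= 0).any():
            raise ValueError("gamma must be positive")
        self.product = product
        self._rows = {
            row["class"]: (row["gamma"], row["c"]) for _, row in self.table.iterrows()
        }

    @classmethod
    def from_csv(cls, path, product: str) -> "SIFGPPCoeffs":
        return cls(pd.read_csv(path), product)

    @classmethod
    def packaged(cls, product: str = "gosif") -> "SIFGPPCoeffs":
        return cls(packaged_table("sif_gpp_coeffs"), product)

    def coeffs(self, cls_name: str) -> tuple[float, float]:
        try:
            return self._rows[cls_name]
        except KeyError:
            raise KeyError(
                f"no SIF-GPP coefficients for class {cls_name!r} "
                f"(product {self.product!r})"
            ) from None

    def __contains__(self, cls_name: str) -> bool:
        return cls_name in self._rows

    def classes(self) -> list[str]:
        return list(self._rows)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(1, "product", self.product)
        out.to_csv(path, index=False)


class RefineScalars:
    """Per-class GPP refinement scalars η (scaling) and ε (additive term)."""

    def __init__(self, table: pd.DataFrame):
        self.table = _per_class_frame(table, {"class", "eta", "epsilon"}, "refinement")
        if not self.table["eta"].map(math.isfinite).all():
            raise ValueError("eta must be finite")
        self._rows = {
            row["class"]: (row["eta"], row["epsilon"])
            for _, row in self.table.iterrows()
        }

    @classmethod
    def from_csv(cls, path) -> "RefineScalars":
        return cls(pd.read_csv(path))

    def scalars(self, cls_name: str) -> tuple[float, float]:
        try:
            return self._rows[cls_name]
        except KeyError:
            raise KeyError(f"no refinement scalars for class {cls_name!r}") from None

    def __contains__(self, cls_name: str) -> bool:
        return cls_name in self._rows

    def classes(self) -> list[str]:
        return list(self._rows)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


#: Predictors entering each refined-respiration experiment.
EXPERIMENT_PREDICTORS = {
    "SM": ("nu", "kappa"),
    "ST": ("tau", "kappa"),
    "SMST": ("tau", "nu", "kappa"),
}


class RecoRefineParams:
    """Per-class refined-respiration coefficients for one experiment.

    ν multiplies volumetric soil moisture (m³ m⁻³), τ multiplies soil
    temperature (K) and κ multiplies the baseline air-temperature
    respiration term α·Tair + β.  ``experiment`` is ``SM``, ``ST`` or
    ``SMST`` and fixes which of ν/τ are present.
    """

    def __init__(self, table: pd.DataFrame, experiment: str):
        if experiment not in EXPERIMENT_PREDICTORS:
            raise ValueError("experiment must be one of 'SM', 'ST', 'SMST'")
        if "experiment" in table.columns:
            table = table[table["experiment"] == experiment].drop(columns="experiment")
        self.table = _per_class_frame(table, {"class", "kappa"}, "Reco refinement")
        self.experiment = experiment
        needed = EXPERIMENT_PREDICTORS[experiment]
        for col in needed:
            if col not in self.table.columns:
                raise ValueError(f"experiment {experiment} requires column {col!r}")
            if not self.table[col].map(lambda v: math.isfinite(float(v))).all():
                raise ValueError(f"non-finite {col} in Reco refinement table")
        self._rows = {
            row["class"]: {col: float(row[col]) for col in needed}
            for _, row in self.table.iterrows()
        }

    @classmethod
    def from_csv(cls, path, experiment: str) -> "RecoRefineParams":
        return cls(pd.read_csv(path), experiment)

    @classmethod
    def packaged(cls, experiment: str = "SMST") -> "RecoRefineParams":
        return cls(packaged_table("reco_refine_params"), experiment)

    def coeffs(self, cls_name: str) -> dict[str, float]:
        try:
            return self._rows[cls_name]
        except KeyError:
            raise KeyError(
                f"no {self.experiment} respiration coefficients for class "
                f"{cls_name!r}"
            ) from None

    def __contains__(self, cls_name: str) -> bool:
        return cls_name in self._rows

    def classes(self) -> list[str]:
        return list(self._rows)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(1, "experiment", self.experiment)
        out.to_csv(path, index=False)
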