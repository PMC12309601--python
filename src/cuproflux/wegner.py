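"""Hill-cooperativity analysis of MAC/ACE copper titrations.

The transcription factors MAC1 (deactivated by Cu binding) and ACE1
(activated by Cu binding) partition between apo and holo forms as a
function of the labile copper pool.  Treating metallation as a single
Hill-type equilibrium, Cu·P ⇌ n CU + P with dissociation constant Kd,
the apo fraction obeys

    [P]/[P_tot] = 1 / ([CU]^n / Kd + 1),

so Kd = [CU]_0.5^n and the 10%–90% dynamic range of the titration is
[CU]_0.1/[CU]_0.9 = 81^(1/n).  Hill coefficients below one indicate
negative cooperativity.

Published titrations were recorded against a hypothetical "free"
(aqueous) Cu axis; because the cytosol contains essentially no aqueous
copper, the axis is rescaled onto the labile-pool (CU) concentration
scale by a single multiplicative anchor.  Rescaling does not change
fitted Hill coefficients.

Ligand concentrations here are in molar (M); ``HillFit`` stores Kd in
units of Mⁿ but reports it on the M scale, as is conventional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TitrationPoint",
    "HillFit",
    "CalibrationAnchor",
    "apo_fraction",
    "hill_coefficient_point",
    "hill_from_dynamic_range",
    "kd_from_half_saturation",
    "fit_hill_curve",
    "recalibrate_axis",
    "synthetic_titration_curve",
    "load_synthetic_wegner_points",
]


@dataclass(frozen=True)
class TitrationPoint:
    ligand_concentration: float  # M
    apo_fraction: float  # [P]/[P_tot], dimensionless

    def __post_init__(self) -> None:
        if not self.ligand_concentration > 0:
            raise ValueError("ligand concentration must be > 0")
        if not 0.0 <= self.apo_fraction <= 1.0:
            raise ValueError("apo fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HillFit:
    """Hill coefficient, half-saturation ligand concentration and Kd."""

    n: float
    cu_half: float  # M
    kd: float  # Mⁿ, reported on the M scale

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("Hill coefficient must be > 0")
        if not self.cu_half > 0:
            raise ValueError("cu_half must be > 0")
        if not math.isclose(self.kd, self.cu_half**self.n, rel_tol=1e-10):
            raise ValueError("kd must equal cu_half ** n")

    @classmethod
    def from_half_saturation(cls, cu_half: float, n: float) -> "HillFit":
        return cls(n=n, cu_half=cu_half, kd=kd_from_half_saturation(cu_half, n))

    def rescaled(self, factor: float) -> "HillFit":
        """The same binding curve on a ligand axis multiplied by ``factor``."""
        if not factor > 0:
            raise ValueError("rescaling factor must be > 0")
        return HillFit.from_half_saturation(self.cu_half * factor, self.n)


@dataclass(frozen=True)
class CalibrationAnchor:
    """Maps the original "free"-Cu axis onto the labile-pool scale.

    ``free_scale_anchor`` is the "free"-Cu concentration (M) asserted to
    correspond to the reference labile-pool concentration ``cu_ref``
    (also M).  The recalibration multiplies every abscissa by
    ``factor = cu_ref / free_scale_anchor``.
    """

    free_scale_anchor: float  # M
    cu_ref: float  # M (labile pool at the reference condition)

    def __post_init__(self) -> None:
        if not self.free_scale_anchor > 0 or not self.cu_ref > 0:
            raise ValueError("anchor concentrations must be > 0")

    @property
    def factor(self) -> float:
        return self.cu_ref / self.free_scale_anchor


def apo_fraction(cu: float, fit: HillFit) -> float:
    """Apo fraction [P]/[P_tot] at ligand concentration ``cu`` (M)."""
    if cu < 0:
        raise ValueError("ligand concentration must be >= 0")
    if cu == 0.0:
        return 1.0
    return 1.0 / (cu**fit.n / fit.kd + 1.0)


def hill_coefficient_point(apo_frac: float, cu: float, cu_half: float) -> float:
    """Per-point Hill coefficient n = log(1/f − 1) / log(cu / cu_half)."""
    if not 0.0 < apo_frac < 1.0:
        raise ValueError("apo fraction must lie strictly in (0, 1)")
    if math.isclose(apo_frac, 0.5, rel_tol=0, abs_tol=1e-12) or math.isclose(
        cu, cu_half, rel_tol=1e-12
    ):
        raise ZeroDivisionError("0/0 at half saturation; point carries no slope information")
    return math.log(1.0 / apo_frac - 1.0) / math.log(cu / cu_half)


def hill_from_dynamic_range(cu_at_10pct: float, cu_at_90pct: float) -> float:
    """Hill coefficient from the 10%/90%-apo dynamic range.

    The ratio of ligand concentrations at 10% and 90% apo fraction is
    81^(1/n); larger cooperativity compresses the range.
    """
    if not (cu_at_10pct > 0 and cu_at_90pct > 0):
        raise ValueError("concentrations must be > 0")
    ratio = cu_at_10pct / cu_at_90pct
    if ratio <= 1.0:
        raise ValueError("dynamic-range ratio must exceed 1")
    return math.log(81.0) / math.log(ratio)


def kd_from_half_saturation(cu_half: float, n: float) -> float:
    """Kd = cu_half ** n (units Mⁿ, reported in M)."""
    if not cu_half > 0 or not n > 0:
        raise ValueError("cu_half and n must be > 0")
    return cu_half**n


def fit_hill_curve(
    points: list[TitrationPoint],
    cu_half: float,
    exclusion_band: tuple[float, float] = (0.45, 0.55),
    usable_range: tuple[float, float] = (0.05, 0.95),
) -> HillFit:
    """Fit a Hill coefficient from titration points given the half point.

    Averages the per-point Hill coefficient over points whose apo
    fraction lies inside ``usable_range`` but outside the indeterminate
    ``exclusion_band`` around 0.5 (the mid-titration points carry the
    information; the extreme tails are dominated by digitization error).
    """
    usable = [
        p
        for p in points
        if usable_range[0] < p.apo_fraction < usable_range[1]
        and not exclusion_band[0] <= p.apo_fraction <= exclusion_band[1]
    ]
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 usable titration points, got {len(usable)}"
        )
    n = float(
        np.mean(
            [
                hill_coefficient_point(p.apo_fraction, p.ligand_concentration, cu_half)
                for p in usable
            ]
        )
    )
    return HillFit.from_half_saturation(cu_half, n)


def recalibrate_axis(
    points: list[TitrationPoint], anchor: CalibrationAnchor
) -> list[TitrationPoint]:
    """Rescale every ligand concentration by the anchor factor.

    Apo fractions are untouched, so Hill coefficients fitted before and
    after recalibration coincide (pure change of ligand units).
    """
    f = anchor.factor
    return [
        TitrationPoint(p.ligand_concentration * f, p.apo_fraction) for p in points
    ]


def synthetic_titration_curve(
    fit: HillFit,
    n_points: int = 20,
    frac_range: tuple[float, float] = (0.02, 0.98),
) -> list[TitrationPoint]:
    """Noise-free titration points sampled evenly in apo fraction.

    Inverts the Hill curve: cu = (Kd (1/f − 1))^(1/n).  Used to rebuild
    titration curves from published summary parameters and as ground
    truth for round-trip tests.
    """
    fracs = np.linspace(frac_range[0], frac_range[1], n_points)
    points = []
    for f in fracs:
        cu = (fit.kd * (1.0 / f - 1.0)) ** (1.0 / fit.n)
        points.append(TitrationPoint(float(cu), float(f)))
    return points


def load_synthetic_wegner_points(protein: str = "MAC") -> list[TitrationPoint]:
    """Shipped synthetic MAC/ACE titration points on the "free"-Cu axis.

    The file is a reconstruction from published summary parameters, not
    digitized measurements; see its header.
    """
    from importlib import resources

    text = (
        resources.files("cuproflux") / "data" / "wegner_points_synthetic.tsv"
    ).read_text()
    points = []
    for line in text.splitlines():
        if line.startswith("#") or line.startswith("protein") or not line.strip():
            continue
        name, cu, frac = line.split("\t")
        if name == protein:
            points.append(TitrationPoint(float(cu), float(frac)))
    if not points:
        raise KeyError(f"no points for protein {protein!r}")
    return points
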