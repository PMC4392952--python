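"""DG/CA3 response index, fitted index curves, and their critical point.

The response index summarises the coupled reaction of the two directly
connected hippocampal subfields to an insult: RI_V = V_DG / V_CA3 for
volume and RI_ND = ND_DG / ND_CA3 for apoptotic numerical density.  Group
means of each index, plotted against the ordered treatment arms coded
Con=1, Ins=2, VitC=3, Dia=4, are fitted by low-degree polynomials; the
"critical point" is where the volume curve and the apoptosis curve
intersect — the index value at which volumetric change and neuronal loss
become coincident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import GROUPS

GROUP_CODES = {"Con": 1, "Ins": 2, "VitC": 3, "Dia": 4}
INDEX_NAMES = ("volume", "density")

#: columns a per-animal measurement table must provide
MEASUREMENT_COLUMNS = ("animal_id", "group", "V_DG", "V_CA3", "ND_DG", "ND_CA3")

_NUMERATOR = {"volume": "V_DG", "density": "ND_DG"}
_DENOMINATOR = {"volume": "V_CA3", "density": "ND_CA3"}


def response_index(numerator: float, denominator: float) -> float:
    """RI = DG quantity / CA3 quantity; scale-invariant by construction."""
    if denominator <= 0:
        raise ValueError("response index denominator must be positive")
    return numerator / denominator


@dataclass(frozen=True)
class ResponseIndexTable:
    """Per-group mean +/- SD of the two response indices.

    ``mode`` records how the table was computed: ``per_animal`` averages the
    per-animal ratios (SDs defined), ``ratio_of_means`` divides group means
    (SDs undefined, reported as NaN).
    """

    means: pd.DataFrame  # index INDEX_NAMES, columns GROUPS
    sds: pd.DataFrame
    mode: str

    def cell(self, which_index: str, group: str, ndigits: int | None = None) -> float:
        v = float(self.means.loc[which_index, group])
        if ndigits is not None:
            v = float(np.round(v, ndigits))  # round-half-even, matching 2-dp reporting
        return v


def index_table(measurements: pd.DataFrame, mode: str = "per_animal") -> ResponseIndexTable:
    """Build the response-index table from per-animal measurements.

    ``per_animal``: group mean and SD of each animal's own DG/CA3 ratio.
    ``ratio_of_means``: ratio of the group-mean DG quantity to the
    group-mean CA3 quantity — the computation that reproduces a published
    summary table when only group means are available.
    """
    if mode not in ("per_animal", "ratio_of_means"):
        raise ValueError("mode must be 'per_animal' or 'ratio_of_means'")
    means = pd.DataFrame(index=list(INDEX_NAMES), columns=list(GROUPS), dtype=float)
    sds = pd.DataFrame(index=list(INDEX_NAMES), columns=list(GROUPS), dtype=float)
    for group in GROUPS:
        sub = measurements[measurements["group"] == group]
        if len(sub) == 0:
            raise ValueError(f"no animals in group {group!r}")
        for which in INDEX_NAMES:
            num = sub[_NUMERATOR[which]].to_numpy(dtype=float)
            den = sub[_DENOMINATOR[which]].to_numpy(dtype=float)
            if mode == "per_animal":
                if np.any(den <= 0):
                    raise ValueError(
                        f"zero/negative {_DENOMINATOR[which]} in group {group!r}: "
                        "per-animal ratio undefined"
                    )
                ratios = num / den
                means.loc[which, group] = ratios.mean()
                sds.loc[which, group] = ratios.std(ddof=1) if len(ratios) > 1 else 0.0
            else:
                means.loc[which, group] = response_index(num.mean(), den.mean())
                sds.loc[which, group] = np.nan
    return ResponseIndexTable(means=means, sds=sds, mode=mode)


def index_table_from_group_means(
    group_means: dict[str, dict[str, dict[str, float]]],
) -> ResponseIndexTable:
    """Ratio-of-means table straight from printed group means.

    ``group_means`` maps quantity ("volume" | "density") -> region
    ("DG" | "CA3") -> group -> mean.
    """
    means = pd.DataFrame(index=list(INDEX_NAMES), columns=list(GROUPS), dtype=float)
    for which in INDEX_NAMES:
        for group in GROUPS:
            means.loc[which, group] = response_index(
                group_means[which]["DG"][group], group_means[which]["CA3"][group]
            )
    sds = pd.DataFrame(np.nan, index=list(INDEX_NAMES), columns=list(GROUPS))
    return ResponseIndexTable(means=means, sds=sds, mode="ratio_of_means")


@dataclass(frozen=True)
class IndexCurve:
    """Least-squares polynomial through the four (group code, index mean) points.

    ``coeffs`` are ascending (c0 + c1 x + c2 x^2 ...).
    """

    which_index: str
    coeffs: tuple[float, ...]
    residuals: tuple[float, ...] = field(default=())

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return np.polynomial.polynomial.polyval(x, self.coeffs)

    def equation(self) -> str:
        terms = [f"{c:+.4g}*x^{k}" if k else f"{c:.4g}" for k, c in enumerate(self.coeffs)]
        return "y = " + " ".join(terms)


def fit_index_curve(table: ResponseIndexTable, which_index: str, degree: int = 1) -> IndexCurve:
    """Fit a polynomial of the given degree to one index across the four arms."""
    if which_index not in INDEX_NAMES:
        raise ValueError(f"which_index must be one of {INDEX_NAMES}")
    x = np.array([GROUP_CODES[g] for g in GROUPS], dtype=float)
    y = table.means.loc[which_index, list(GROUPS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("all four group means must be present and finite")
    if degree >= len(x):
        raise ValueError("polynomial degree must be below the number of group points")
    if degree > 2:
        raise ValueError("degree above 2 is not supported")
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = np.polynomial.polynomial.polyval(x, coeffs) - y
    return IndexCurve(which_index=which_index, coeffs=tuple(coeffs), residuals=tuple(resid))


@dataclass(frozen=True)
class CriticalPoint:
    """Intersection of the two fitted index curves."""

    x_star: float  # group-scale coordinate
    y_star: float  # shared index value at the intersection


class NoIntersectionError(ValueError):
    """The two fitted curves do not meet within the search range."""


def critical_point(
    curve_v: IndexCurve,
    curve_nd: IndexCurve,
    x_range: tuple[float, float] = (1.0, 6.0),
) -> CriticalPoint:
    """Locate where the volume-index and density-index curves coincide.

    For two linear fits the closed-form intersection is used; for higher
    degrees the real roots of the difference polynomial are searched within
    ``x_range`` and the smallest in-range root is returned.
    """
    cv = np.asarray(curve_v.coeffs, dtype=float)
    cn = np.asarray(curve_nd.coeffs, dtype=float)
    k = max(cv.size, cn.size)
    diff = np.zeros(k)
    diff[: cv.size] += cv
    diff[: cn.size] -= cn
    if np.allclose(diff, 0.0, atol=1e-15):
        raise ValueError("curves are identical: intersection is not a point")
    diff = np.trim_zeros(diff, trim="b")
    if diff.size <= 1:
        raise NoIntersectionError("parallel distinct curves never intersect")
    if diff.size == 2:  # linear difference: closed form
        roots = np.array([-diff[0] / diff[1]])
    else:
        roots = np.polynomial.polynomial.polyroots(diff)
    real = roots[np.abs(roots.imag) < 1e-12].real if np.iscomplexobj(roots) else roots
    in_range = real[(real >= x_range[0] - 1e-12) & (real <= x_range[1] + 1e-12)]
    if in_range.size == 0:
        raise NoIntersectionError(
            f"no real intersection in x range {x_range}; roots at {np.sort(real)}"
        )
    x_star = float(np.sort(in_range)[0])
    y_v = float(curve_v(x_star))
    y_n = float(curve_nd(x_star))
    if abs(y_v - y_n) > 1e-9:
        raise ArithmeticError("intersection residual exceeds 1e-9")
    return CriticalPoint(x_star=x_star, y_star=y_v)
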