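"""Registry of published GAT-correction formulas.

Each formula maps a Goldmann applanation reading (mmHg) plus, depending on
the formula, central corneal thickness (µm), corneal radius (mm) and age
(years) to a corneal-property-adjusted IOP estimate.  All formulas are pure
functions over numpy arrays; per-record evaluation goes through
:func:`correct` and whole-cohort evaluation through :func:`correct_cohort`.

Unit convention at the boundary: CCT in micrometres, radius in millimetres.
Formulas published in millimetre thickness units convert internally.

Several printed sources are typographically ambiguous; the normative
readings implemented here are documented per formula (see the `variant`
parameters and the package README).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .cohort import Cohort, EyeRecord
from .errors import DependencyError, InsufficientDataError, NonPhysiologicalIOPWarning, NumericError

ArrayLike = np.ndarray

FORMULA_IDS = (
    "shimmyo",
    "shimmyo_r",
    "elsheikh2009",
    "elsheikh2011",
    "srodka",
    "chihara",
    "doughty",
    "foster",
    "kohlhaas",
    "ehlers",
)


@dataclass(frozen=True)
class CorrectionFormula:
    """A named, parameterized correction.

    Attributes
    ----------
    formula_id : str
        Registry key.
    requires : frozenset of {"cct", "r", "age"}
        Record fields the formula needs beyond the GAT reading.
    params : dict
        Named constants; overriding must keep the declared units.
    func : callable
        ``func(gat, cct_um, r_mm, age, params) -> corrected`` on arrays.
    """

    formula_id: str
    requires: frozenset
    params: dict
    func: Callable[..., ArrayLike]

    def with_params(self, **overrides) -> "CorrectionFormula":
        params = {**self.params, **overrides}
        unknown = set(overrides) - set(self.params)
        if unknown:
            raise NumericError(
                f"{self.formula_id}: unknown parameter(s) {sorted(unknown)}"
            )
        return replace(self, params=params)


# ---------------------------------------------------------------------------
# Individual formulas
# ---------------------------------------------------------------------------

def _shimmyo_delta(gat, cct_um, params):
    # Printed source is ambiguous about the denominator's exponent; three
    # readings are selectable. "linear" (default): delta = (550 - CCT)/18.
    base = (params["cct_ref_um"] - cct_um) / params["divisor"]
    variant = params["variant"]
    if variant == "linear":
        return base
    if variant == "power":
        # base scaled by divisor**(0.005*gat): (550-CCT) * 18**(0.005*gat - 1)
        return base * params["divisor"] ** (params["exponent_slope"] * gat)
    if variant == "literal":
        # divisor raised to a negative exponent: (550-CCT) * 18**(0.005*gat)
        return (params["cct_ref_um"] - cct_um) * params["divisor"] ** (
            params["exponent_slope"] * gat
        )
    raise NumericError(f"unknown shimmyo variant {variant!r}")


def _shimmyo(gat, cct_um, r_mm, age, params):
    return gat + _shimmyo_delta(gat, cct_um, params)


def _shimmyo_r(gat, cct_um, r_mm, age, params):
    return (
        gat
        + _shimmyo_delta(gat, cct_um, params)
        + params["r_slope"] * (r_mm - params["r_ref_mm"])
    )


def _polyval(coeffs, x):
    # coeffs ascending: c0 + c1*x + c2*x^2 + ...
    out = np.zeros_like(np.asarray(x, dtype=float))
    for k, c in enumerate(coeffs):
        out = out + c * np.asarray(x, dtype=float) ** k
    return out


def _elsheikh(gat, cct_um, r_mm, age, params):
    # IOPc = GAT / (A_CCT * A_R * A_age * A_IOP); each A is a config-supplied
    # polynomial (identity, i.e. constant 1, by default -- the source
    # coefficients are not bundled).
    a = np.ones_like(np.asarray(gat, dtype=float))
    for key, x in (
        ("a_cct", cct_um),
        ("a_r", r_mm),
        ("a_age", age),
        ("a_iop", gat),
    ):
        coeffs = params[key]
        if len(coeffs) > 1 and x is None:
            raise DependencyError(f"elsheikh coefficient {key} needs its input field")
        a = a * (_polyval(coeffs, x if x is not None else 0.0))
    if np.any(a <= 0):
        raise NumericError("elsheikh correction factor must be strictly positive")
    return gat / a


def _srodka(gat, cct_um, r_mm, age, params):
    # Closed form: multiplier * (IOP_CA + 3) - 3, where the geometric
    # multiplier is e*(CCT_c - (R/R_c)*CCT_mm) + 1 (thickness in mm) and
    # IOP_CA is the quadratic calibration of the raw GAT reading.
    cct_mm = cct_um / 1000.0
    mult = params["e_per_mm"] * (
        params["cct_ref_mm"] - (r_mm / params["r_ref_mm"]) * cct_mm
    ) + 1.0
    iop_ca = params["ca0"] + params["ca1"] * gat + params["ca2"] * gat ** 2
    return mult * (iop_ca + 3.0) - 3.0


def _chihara(gat, cct_um, r_mm, age, params):
    # Thickness and radius in mm, as the printed constants imply; under this
    # convention the structural fraction is ~2e-7 and the correction is
    # numerically GAT + 4.15.  A micrometre variant is kept for sensitivity
    # analysis (units="um").
    if params["units"] == "mm":
        cct = cct_um / 1000.0
        r = r_mm
    elif params["units"] == "um":
        cct = cct_um
        r = r_mm * 1000.0
    else:
        raise NumericError(f"unknown chihara units {params['units']!r}")
    frac = (
        params["k"] * cct ** 2
        / (params["area_mm2"] * (r * 1e3 - cct / 2.0) * 1e4)
    )
    return (gat + params["offset"]) / (frac + 1.0)


def _doughty(gat, cct_um, r_mm, age, params):
    return gat + params["scale"] * (params["cct_ref_um"] - cct_um) / params["cct_ref_um"]


def _foster(gat, cct_um, r_mm, age, params):
    return params["slope"] * gat + params["intercept"]


def _kohlhaas(gat, cct_um, r_mm, age, params):
    return gat + params["slope"] * cct_um + params["intercept"]


def _ehlers(gat, cct_um, r_mm, age, params):
    # Printed bracket structure is corrupt; the recoverable reading is the
    # classic per-thickness offset CF = 0.071 * (520 - CCT).
    return gat + params["slope_per_um"] * (params["cct_ref_um"] - cct_um)


def _build_registry() -> dict[str, CorrectionFormula]:
    shimmyo_params = {
        "cct_ref_um": 550.0,
        "divisor": 18.0,
        "variant": "linear",
        "exponent_slope": 0.005,
    }
    return {
        "shimmyo": CorrectionFormula(
            "shimmyo", frozenset({"cct"}), dict(shimmyo_params), _shimmyo
        ),
        "shimmyo_r": CorrectionFormula(
            "shimmyo_r",
            frozenset({"cct", "r"}),
            {**shimmyo_params, "r_slope": 0.8, "r_ref_mm": 7.848837},
            _shimmyo_r,
        ),
        "elsheikh2009": CorrectionFormula(
            "elsheikh2009",
            frozenset(),
            {"a_cct": (1.0,), "a_r": (1.0,), "a_age": (1.0,), "a_iop": (1.0,)},
            _elsheikh,
        ),
        "elsheikh2011": CorrectionFormula(
            "elsheikh2011",
            frozenset(),
            {"a_cct": (1.0,), "a_r": (1.0,), "a_age": (1.0,), "a_iop": (1.0,)},
            _elsheikh,
        ),
        "srodka": CorrectionFormula(
            "srodka",
            frozenset({"cct", "r"}),
            {
                "cct_ref_mm": 0.550,
                "r_ref_mm": 7.8,
                "e_per_mm": 1.0,
                "ca0": -1.61,
                "ca1": 0.94,
                "ca2": 0.011,
            },
            _srodka,
        ),
        "chihara": CorrectionFormula(
            "chihara",
            frozenset({"cct", "r"}),
            {"offset": 4.15, "k": 19.09, "area_mm2": 0.34, "units": "mm"},
            _chihara,
        ),
        "doughty": CorrectionFormula(
            "doughty", frozenset({"cct"}), {"scale": 25.0, "cct_ref_um": 545.0}, _doughty
        ),
        "foster": CorrectionFormula(
            "foster", frozenset(), {"slope": 1.08, "intercept": 5.5}, _foster
        ),
        "kohlhaas": CorrectionFormula(
            "kohlhaas", frozenset({"cct"}), {"slope": -0.0423, "intercept": 23.28}, _kohlhaas
        ),
        "ehlers": CorrectionFormula(
            "ehlers", frozenset({"cct"}), {"slope_per_um": 0.071, "cct_ref_um": 520.0}, _ehlers
        ),
    }


REGISTRY: dict[str, CorrectionFormula] = _build_registry()


def get_formula(formula_id: str, overrides: Mapping | None = None) -> CorrectionFormula:
    """Look up a formula by id, optionally overriding constants."""
    if formula_id not in REGISTRY:
        raise KeyError(
            f"unknown formula {formula_id!r}; known: {', '.join(sorted(REGISTRY))}"
        )
    formula = REGISTRY[formula_id]
    if overrides:
        formula = formula.with_params(**overrides)
    # Polynomial elsheikh coefficients introduce input requirements.
    if formula.func is _elsheikh:
        req = set(formula.requires)
        for key, dep in (("a_cct", "cct"), ("a_r", "r"), ("a_age", "age")):
            if len(formula.params[key]) > 1:
                req.add(dep)
        formula = replace(formula, requires=frozenset(req))
    return formula


def _check_result(formula_id: str, out: np.ndarray) -> None:
    if np.any(~np.isfinite(out)):
        raise NumericError(f"{formula_id}: correction produced a non-finite value")
    if np.any(out <= 0):
        warnings.warn(
            f"{formula_id}: corrected IOP <= 0 mmHg (value returned unclamped)",
            NonPhysiologicalIOPWarning,
            stacklevel=3,
        )


def correct(
    formula_id: str,
    record: EyeRecord,
    overrides: Mapping | None = None,
) -> float:
    """Apply one correction formula to one record; returns corrected mmHg.

    Raises
    ------
    DependencyError
        If the record lacks a field the formula requires.
    NumericError
        If evaluation produces a non-finite value.
    """
    formula = get_formula(formula_id, overrides)
    r_mm = record.radius_mm
    if "r" in formula.requires and r_mm is None:
        raise DependencyError(
            f"{formula_id} requires corneal curvature (r_mm or km_D) "
            f"missing on subject {record.subject_id!r}"
        )
    out = formula.func(
        np.float64(record.iop_gat),
        np.float64(record.cct_um),
        np.float64(r_mm) if r_mm is not None else None,
        np.float64(record.age),
        formula.params,
    )
    out = np.asarray(out, dtype=float)
    _check_result(formula_id, out)
    return float(out)


def correct_cohort(
    formula_id: str,
    cohort: Cohort,
    overrides: Mapping | None = None,
) -> np.ndarray:
    """Vectorized correction over a cohort, aligned to record order."""
    if len(cohort) == 0:
        raise InsufficientDataError("cannot correct an empty cohort")
    formula = get_formula(formula_id, overrides)
    r = cohort.radius_mm
    if "r" in formula.requires and np.any(np.isnan(r)):
        bad = int(np.flatnonzero(np.isnan(r))[0])
        raise DependencyError(
            f"{formula_id} requires corneal curvature; missing at row {bad} "
            f"(subject {cohort[bad].subject_id!r})"
        )
    out = formula.func(
        cohort.iop_gat, cohort.cct_um, r, cohort.age, formula.params
    )
    out = np.broadcast_to(np.asarray(out, dtype=float), (len(cohort),)).copy()
    _check_result(formula_id, out)
    return out


__all__ = [
    "CorrectionFormula",
    "REGISTRY",
    "FORMULA_IDS",
    "get_formula",
    "correct",
    "correct_cohort",
]
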