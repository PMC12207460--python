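"""Dimensional audit of the model equations.

Every term of the five field equations is dimension-checked symbolically
at startup (or on demand) using exponent bookkeeping over the package's
base units: length (μm), time (h), cell density (μm⁻³ ≡ length⁻³) and
chemokine concentration (nM, an independent base unit here).

A dimension is represented as a tuple ``(length, time, conc)`` of integer
exponents; cell densities carry ``length=-3``.
"""

from __future__ import annotations

from .params import ModelParams, InvalidParameterError

Dim = tuple[int, int, int]  # (length, time, nM)

# base quantities
DENSITY: Dim = (-3, 0, 0)          # cell density, μm⁻³
CONC: Dim = (0, 0, 1)              # chemokine, nM
PER_HOUR: Dim = (0, -1, 0)
DIFFUSIVITY: Dim = (2, -1, 0)      # μm²/h
GRAD = (-1, 0, 0)                  # ∇ adds μm⁻¹
LAPL = (-2, 0, 0)                  # ∇² adds μm⁻²
DIMLESS: Dim = (0, 0, 0)


def _mul(*dims: Dim) -> Dim:
    out = [0, 0, 0]
    for d in dims:
        for i in range(3):
            out[i] += d[i]
    return tuple(out)  # type: ignore[return-value]


def _inv(d: Dim) -> Dim:
    return (-d[0], -d[1], -d[2])


# dimensions of the parameters under the package's unit convention
PARAM_DIMS: dict[str, Dim] = {
    "D_C": DIFFUSIVITY,
    "D_T": DIFFUSIVITY,
    "D_M": DIFFUSIVITY,
    # v_C = T·χ(ρC)·∇ρC must be μm/h with χ in nM⁻¹ and ∇ρC in nM/μm
    "T_chi": DIFFUSIVITY,
    "K_offon": CONC,
    "p": _mul(DENSITY, PER_HOUR),
    "mu": DENSITY,
    "d": PER_HOUR,
    "k_r": _mul(_inv(DENSITY), PER_HOUR),
    "k_b": _mul(_inv(DENSITY), PER_HOUR),
    "K_cap": DENSITY,
    "k_m": PER_HOUR,
    "k_e": _mul(CONC, _inv(DENSITY), PER_HOUR),
    "k_c": PER_HOUR,
    "k_ex": PER_HOUR,
}


def audit_units(params: ModelParams | None = None) -> dict[str, Dim]:
    """Dimension-check every term of the five field equations.

    Returns a mapping ``equation/term -> dimension`` for all checked terms,
    raising :class:`InvalidParameterError` on any mismatch.  The parameter
    values themselves are irrelevant; only the unit convention is audited.
    """
    P = PARAM_DIMS
    chi = _inv(CONC)                          # χ = K/(K+ρC)², nM⁻¹
    v_c = _mul(P["T_chi"], chi, CONC, GRAD)   # drift velocity
    if v_c != (1, -1, 0):
        raise InvalidParameterError(f"drift velocity has dimension {v_c}, expected μm/h")

    cell_rate = _mul(DENSITY, PER_HOUR)
    conc_rate = _mul(CONC, PER_HOUR)

    terms: dict[str, Dim] = {
        # thymocyte equation, all terms must be μm⁻³ h⁻¹
        "T/diffusion": _mul(P["D_T"], LAPL, DENSITY),
        "T/advection": _mul(GRAD, DENSITY, v_c),
        "T/activation": _mul(P["k_r"], DENSITY, DENSITY),
        "T/production": P["p"],                   # φ is dimensionless
        "T/exit": _mul(P["k_ex"], DENSITY),
        # activated thymocytes
        "Tstar/diffusion": _mul(P["D_T"], LAPL, DENSITY),
        "Tstar/advection": _mul(GRAD, DENSITY, v_c),
        "Tstar/activation": _mul(P["k_r"], DENSITY, DENSITY),
        "Tstar/deletion": _mul(P["d"], DENSITY),
        # mTECs (logistic factor dimensionless)
        "M/diffusion": _mul(P["D_M"], LAPL, DENSITY),
        "M/birth": _mul(P["k_b"], DENSITY, DENSITY),
        "M/decay": _mul(P["k_m"], DENSITY),
        # chemokine, nM h⁻¹
        "C/diffusion": _mul(P["D_C"], LAPL, CONC),
        "C/emission": _mul(P["k_e"], DENSITY),
        "C/decay": _mul(P["k_c"], CONC),
        # tolerant thymocytes
        "T0/production": P["p"],
        "T0/exit": _mul(P["k_ex"], DENSITY),
    }

    for name, dim in terms.items():
        expected = conc_rate if name.startswith("C/") else cell_rate
        if dim != expected:
            raise InvalidParameterError(
                f"term {name} has dimension {dim}, expected {expected}"
            )
    # dimensionless checks
    if _mul(DENSITY, _inv(P["mu"])) != DIMLESS:
        raise InvalidParameterError("ρM/μ is not dimensionless")
    if _mul(DENSITY, _inv(P["K_cap"])) != DIMLESS:
        raise InvalidParameterError("ρM/K is not dimensionless")
    return terms
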