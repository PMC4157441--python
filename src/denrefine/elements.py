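"""Per-element constants used across the package.

Masses in amu, covalent and van der Waals radii in Å.  Form factors are
one-Gaussian-plus-constant fits f(s) = a·exp(-b·s²) + c with s = 1/d in Å⁻¹,
least-squares fitted to standard 4-Gaussian X-ray scattering tables over
s ∈ [0, 0.6] Å⁻¹ (worst-case fit error ≤ 0.14 e).  The same table is used for
simulated observations and for model structure factors, so only internal
consistency matters for refinement behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElementData:
    symbol: str
    mass: float          # amu
    r_covalent: float    # Å
    r_vdw: float         # Å
    ff_a: float          # e
    ff_b: float          # Å²
    ff_c: float          # e


ELEMENTS: dict[str, ElementData] = {
    "H": ElementData("H", 1.008, 0.31, 1.20, 0.8013, 4.8260, 0.1960),
    "C": ElementData("C", 12.011, 0.76, 1.70, 3.8443, 6.2768, 2.1354),
    "N": ElementData("N", 14.007, 0.71, 1.55, 4.5655, 4.7540, 2.4193),
    "O": ElementData("O", 15.999, 0.66, 1.52, 5.1832, 3.8255, 2.8062),
    "S": ElementData("S", 32.06, 1.05, 1.80, 7.5270, 6.5386, 8.4265),
    "P": ElementData("P", 30.974, 1.07, 1.80, 6.6326, 7.5956, 8.3040),
}


class UnknownElementError(KeyError):
    """Raised when an element has no tabulated mass/scattering data."""


def element_data(symbol: str) -> ElementData:
    try:
        return ELEMENTS[symbol.upper().strip()]
    except KeyError:
        raise UnknownElementError(
            f"element {symbol!r} has no tabulated mass/form-factor data"
        ) from None


def form_factor(symbol: str, s2) -> "float":
    """X-ray form factor f(s) for scattering vector magnitude squared s² = 1/d²."""
    import numpy as np

    el = element_data(symbol)
    return el.ff_a * np.exp(-el.ff_b * s2) + el.ff_c
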