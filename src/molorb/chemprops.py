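"""Conceptual-DFT reactivity descriptors from orbital or state energies.

Two equivalent routes give the electronegativity χ and chemical hardness η
of a species:

* from frontier orbital energies,
      χ = -(ε_HOMO + ε_LUMO) / 2,      η = -(ε_HOMO - ε_LUMO) / 2;
* from the ionization potential and electron affinity,
      χ = (IP + EA) / 2,               η = (IP - EA) / 2,
  where IP = E(X⁺) - E(X) and EA = E(X) - E(X⁻) are total-energy
  differences of the charged and neutral species.

Under the Koopmans identification IP = -ε_HOMO, EA = -ε_LUMO the two routes
coincide exactly.  The chemical potential is μ = -χ.  A negative hardness
(LUMO below HOMO, or EA above IP) is physically anomalous but can occur with
approximate electronic-structure data, so it raises a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OrbitalEnergies:
    """Frontier orbital energies in eV."""

    e_homo: float
    e_lumo: float

    def __post_init__(self):
        if not (np.isfinite(self.e_homo) and np.isfinite(self.e_lumo)):
            raise ValueError("orbital energies must be finite")
        if self.e_lumo < self.e_homo:
            warnings.warn(
                f"LUMO energy ({self.e_lumo}) below HOMO ({self.e_homo}); "
                "hardness will be negative",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StateEnergies:
    """Born-Oppenheimer total energies of neutral/cationic/anionic species."""

    e_neutral: float
    e_cation: float
    e_anion: float

    def __post_init__(self):
        vals = (self.e_neutral, self.e_cation, self.e_anion)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("state energies must be finite")


@dataclass(frozen=True)
class ChemProps:
    """χ, η, μ (all eV) with the protocol that produced them."""

    chi: float
    eta: float
    mu: float
    protocol: str  # "orbital" or "ipea"
    ip: float | None = None
    ea: float | None = None


def props_from_orbitals(orb: OrbitalEnergies) -> ChemProps:
    """Electronegativity and hardness from HOMO/LUMO energies."""
    chi = -0.5 * (orb.e_homo + orb.e_lumo)
    eta = -0.5 * (orb.e_homo - orb.e_lumo)
    if eta < 0:
        warnings.warn(f"negative hardness ({eta} eV)", stacklevel=2)
    return ChemProps(chi=chi, eta=eta, mu=-chi, protocol="orbital")


def ip_ea_from_states(st: StateEnergies) -> tuple[float, float]:
    """IP and EA from total energies of the charged and neutral species."""
    return st.e_cation - st.e_neutral, st.e_neutral - st.e_anion


def props_from_ipea(ip: float, ea: float) -> ChemProps:
    """Electronegativity and hardness from IP and EA."""
    if not (np.isfinite(ip) and np.isfinite(ea)):
        raise ValueError("IP and EA must be finite")
    chi = 0.5 * (ip + ea)
    eta = 0.5 * (ip - ea)
    if eta < 0:
        warnings.warn(f"negative hardness ({eta} eV)", stacklevel=2)
    return ChemProps(chi=chi, eta=eta, mu=-chi, protocol="ipea", ip=ip, ea=ea)


def props_table(df: pd.DataFrame) -> pd.DataFrame:
    """Batch mode: (id, e_homo, e_lumo) table -> (id, chi, eta) table."""
    for col in ("id", "e_homo", "e_lumo"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    chi = -0.5 * (df["e_homo"].to_numpy() + df["e_lumo"].to_numpy())
    eta = -0.5 * (df["e_homo"].to_numpy() - df["e_lumo"].to_numpy())
    if np.any(eta < 0):
        warnings.warn(
            f"{int((eta < 0).sum())} species with negative hardness",
            stacklevel=2,
        )
    return pd.DataFrame({"id": df["id"], "chi": chi, "eta": eta})
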