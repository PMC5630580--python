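"""Model parameters for the microbial redox ecosystem model.

The parameter set describes three bacterial functional groups — cyanobacteria
(CB, oxygenic phototrophs), phototrophic sulfur bacteria (PB, anoxygenic
phototrophs oxidizing sulfide) and sulfate-reducing bacteria (SB) — and four
substrates: oxidized sulfur ``S_O`` (sulfate), reduced sulfur ``S_R``
(sulfide), oxygen ``O`` and phosphorus ``P``.

Units throughout: populations in cells per litre, substrate concentrations
in uM, time in hours.

The default values returned by :func:`default_parameters` are a *calibrated*
set, not a published one: rates, half-saturation and half-inhibition
constants, yields and background concentrations lie in ranges typical of
freshwater-lake microbial communities and were tuned so that the model is
bistable (distinct oxic and anoxic attractors) at a background phosphorus of
9.5 uM and an oxygen diffusivity of 8e-4 per hour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = ["ModelParameters", "default_parameters"]


#: fields that must be strictly positive (rates, yields, half constants)
_STRICTLY_POSITIVE = frozenset(
    {
        "g_max_CB", "g_max_PB", "g_max_SB",
        "K_CB_P", "K_PB_P", "K_SB_P", "K_PB_SR", "K_SB_SO",
        "H_CB_SR", "H_PB_O", "H_SB_O",
        "y_PB_S", "y_SB_S", "y_CB_P", "y_PB_P", "y_SB_P",
    }
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, half constants, yields and boundary conditions.

    Attributes
    ----------
    g_max_CB, g_max_PB, g_max_SB : float
        Maximum specific growth rates (1/h).
    K_CB_P, K_PB_P, K_SB_P : float
        Phosphorus half-saturation constants (uM).
    K_PB_SR : float
        Half-saturation of PB growth on reduced sulfur (uM).
    K_SB_SO : float
        Half-saturation of SB growth on oxidized sulfur (uM).
    H_CB_SR : float
        Half-inhibition of CB by reduced sulfur (uM).
    H_PB_O, H_SB_O : float
        Half-inhibition of PB and SB by oxygen (uM).
    y_PB_S, y_SB_S : float
        Sulfur yields (cells per umole of sulfur turned over).
    y_CB_P, y_PB_P, y_SB_P : float
        Phosphorus yields (cells per umole of phosphorus consumed).
    m_CB, m_PB, m_SB : float
        Mortality rates (1/h), e.g. grazing or viral lysis.
    p_CB : float
        Oxygen production per cyanobacterial cell (umole/cell); multiplies
        the realized specific growth rate in the oxygen balance.
    c : float
        Abiotic (plus chemolithotrophic) oxidation rate constant of reduced
        sulfur by oxygen (1/(uM h)).
    alpha_S, alpha_O, alpha_P : float
        Diffusive-exchange coefficients with the background (1/h). alpha_O
        is the control parameter mimicking mixing across the thermocline.
    S_O_b, S_R_b, O_b, P_b : float
        Background (boundary) concentrations (uM).
    """

    g_max_CB: float
    g_max_PB: float
    g_max_SB: float
    K_CB_P: float
    K_PB_P: float
    K_SB_P: float
    K_PB_SR: float
    K_SB_SO: float
    H_CB_SR: float
    H_PB_O: float
    H_SB_O: float
    y_PB_S: float
    y_SB_S: float
    y_CB_P: float
    y_PB_P: float
    y_SB_P: float
    m_CB: float
    m_PB: float
    m_SB: float
    p_CB: float
    c: float
    alpha_S: float
    alpha_O: float
    alpha_P: float
    S_O_b: float
    S_R_b: float
    O_b: float
    P_b: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"parameter {f.name!r} must be a number, got {v!r}")
            object.__setattr__(self, f.name, float(v))
            v = float(v)
            if v < 0.0:
                raise ValueError(f"parameter {f.name!r} must be >= 0, got {v}")
            if f.name in _STRICTLY_POSITIVE and v == 0.0:
                raise ValueError(f"parameter {f.name!r} must be > 0")

    # -- construction helpers -------------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown parameter name(s): {sorted(unknown)}; "
                f"valid names are {sorted(known)}"
            )
        missing = known - set(d)
        if missing:
            raise KeyError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**d)

    # -- plain-text config round-trip -----------------------------------------

    def to_file(self, path: Union[str, Path]) -> None:
        """Write the parameter set as a plain-text ``key: value`` file."""
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=False)
        )

    @classmethod
    def from_file(cls, path: Union[str, Path], base: "ModelParameters" = None) -> "ModelParameters":
        """Load a parameter set from a ``key: value`` file.

        If *base* is given, the file may specify only a subset of names and
        the remainder is taken from *base*; unknown names always raise.
        """
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: expected a mapping of parameter names to values")
        if base is not None:
            merged = base.to_dict()
            known = set(merged)
            unknown = set(d) - known
            if unknown:
                raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
            merged.update(d)
            return cls.from_dict(merged)
        return cls.from_dict(d)


def default_parameters(**overrides: float) -> ModelParameters:
    """The package's calibrated default parameter set.

    Calibrated (not published) values in freshwater-plausible ranges; the
    set is bistable at ``P_b=9.5`` uM, ``alpha_O=8e-4`` /h. Keyword
    arguments override individual fields.
    """
    base = ModelParameters(
        g_max_CB=0.05,      # 1/h
        g_max_PB=0.07,
        g_max_SB=0.1,
        K_CB_P=0.5,         # uM
        K_PB_P=0.5,
        K_SB_P=0.5,
        K_PB_SR=10.0,
        K_SB_SO=5.0,
        H_CB_SR=300.0,      # uM
        H_PB_O=100.0,
        H_SB_O=100.0,
        y_PB_S=3.33e7,      # cells per umole S
        y_SB_S=3.33e7,
        y_CB_P=1.67e8,      # cells per umole P
        y_PB_P=1.67e8,
        y_SB_P=1.67e8,
        m_CB=0.02,          # 1/h
        m_PB=0.028,
        m_SB=0.04,
        p_CB=6e-9,          # umole O2 per cell
        c=4e-5,             # 1/(uM h)
        alpha_S=0.001,      # 1/h
        alpha_O=8e-4,
        alpha_P=0.01,
        S_O_b=300.0,        # uM
        S_R_b=300.0,
        O_b=300.0,
        P_b=9.5,
    )
    return base.replace(**overrides) if overrides else base
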