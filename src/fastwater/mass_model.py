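"""Mass repartitioning and rescaling of 3-site water.

A "fast water" model is built from a reference 3-site model in two steps:

1. *Repartitioning*: a mass ``m_r`` is moved from the oxygen to the two
   hydrogens symmetrically, ``m_O,r = m_O - m_r`` and ``m_H,r = m_H + m_r/2``.
   This slows the fastest librational motions and stabilises time
   integration at a fixed time step.
2. *Rescaling*: all site masses are multiplied by ``m_tot/M_0`` so the
   molecular mass becomes ``m_tot``.  Because configuration-space averages
   are independent of masses, this leaves all equilibrium properties
   untouched while reducing the solvent viscosity by ``sqrt(m_tot/M_0)``.

The module also provides the time-step/mass equivalence (scaling all
masses by ``f**2`` is formally identical to scaling the time step by
``f``), the ideal square-root scaling laws for self-diffusion and shear
viscosity, and an editor that writes the new masses into a GROMACS
TOP/ITP topology.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .constants import TIP3P_M_H, TIP3P_M_O, TIP3P_M_TOT
from .errors import (
    InvalidArgumentError,
    InvalidSpecError,
    MissingMoleculeError,
    UnsupportedTopologyError,
)

__all__ = [
    "WaterModelMasses",
    "RepartitionSpec",
    "TIP3P",
    "TIP3P_F",
    "repartition_and_rescale",
    "equivalent_time_step",
    "mass_for_time_step",
    "ideal_diffusion_scaling",
    "viscosity_scaling",
    "apply_to_topology",
    "model_card",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class WaterModelMasses:
    """Per-site and total masses (g/mol) of a 3-site water model."""

    m_O: float
    m_H: float
    m_tot: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.m_O > 0 and self.m_H > 0 and self.m_tot > 0):
            raise InvalidSpecError("all masses must be positive")
        if not math.isclose(self.m_O + 2.0 * self.m_H, self.m_tot,
                            rel_tol=_REL_TOL):
            raise InvalidSpecError(
                f"m_O + 2 m_H = {self.m_O + 2 * self.m_H!r} does not match "
                f"m_tot = {self.m_tot!r}")

    def published(self, decimals: int = 3) -> "WaterModelMasses":
        """Round site masses for publication, preserving the total mass.

        The hydrogen mass is rounded to ``decimals`` decimals and the
        oxygen mass is assigned the exact remainder ``m_tot - 2 m_H``, so
        the three published site masses sum to the target total exactly.
        Plain per-site rounding would not: a topology built from it would
        carry a slightly wrong molecular mass.
        """
        m_h = round(self.m_H, decimals)
        m_o = round(self.m_tot - 2.0 * m_h, 12)  # drop float dust only
        return replace(self, m_O=m_o, m_H=m_h)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "m_O_g_per_mol": self.m_O,
            "m_H_g_per_mol": self.m_H,
            "m_tot_g_per_mol": self.m_tot,
        }


#: Unmodified reference model (CHARMM-style TIP3P masses).
TIP3P = WaterModelMasses(TIP3P_M_O, TIP3P_M_H, TIP3P_M_TOT, label="TIP3P")

#: The fast water model: m_r = 4 g/mol repartitioned, total rescaled to
#: 1.116 g/mol, site masses as published (total-preserving 3-decimal values).
TIP3P_F = WaterModelMasses(0.744, 0.186, 1.116, label="TIP3P-F")


@dataclass(frozen=True)
class RepartitionSpec:
    """Specification of a repartition-and-rescale operation.

    ``m_r`` is the mass (g/mol) moved from oxygen to the hydrogens;
    ``m_tot_target`` the final molecular mass.  ``reference`` holds the
    unmodified model the operation starts from.
    """

    m_r: float
    m_tot_target: float
    reference: WaterModelMasses = field(default=TIP3P)

    def __post_init__(self) -> None:
        if self.m_r < 0:
            raise InvalidSpecError("repartitioned mass m_r must be >= 0")
        if self.m_r >= self.reference.m_O:
            raise InvalidSpecError(
                f"m_r = {self.m_r} would leave oxygen with non-positive mass "
                f"(reference m_O = {self.reference.m_O})")
        if self.m_tot_target <= 0:
            raise InvalidSpecError("target total mass must be positive")

    @property
    def scale_factor_sq(self) -> float:
        """Mass scale factor f**2 = m_tot_target / M_0."""
        return self.m_tot_target / self.reference.m_tot


def repartition_and_rescale(spec: RepartitionSpec) -> WaterModelMasses:
    """Apply symmetric O->H repartitioning followed by total-mass rescaling.

    Returns the new site masses
    ``m_O' = (m_O - m_r) * (m_tot/M_0)`` and
    ``m_H' = (m_H + m_r/2) * (m_tot/M_0)``,
    whose total equals ``spec.m_tot_target`` exactly.
    """
    s = spec.scale_factor_sq
    m_o = (spec.reference.m_O - spec.m_r) * s
    m_h = (spec.reference.m_H + spec.m_r / 2.0) * s
    label = f"repartitioned(m_r={spec.m_r:g}, m_tot={spec.m_tot_target:g})"
    return WaterModelMasses(m_o, m_h, m_o + 2.0 * m_h, label=label)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise InvalidArgumentError(f"{name} must be > 0, got {value!r}")


def equivalent_time_step(dt: float, m_tot: float, m_ref: float) -> float:
    """Time step (fs) probed by mass-scaled water at a nominal step ``dt``.

    Scaling all masses by f**2 is equivalent to scaling the time step by f;
    a model of total mass ``m_tot`` run at ``dt`` therefore probes an
    effective step ``dt * sqrt(m_ref / m_tot)`` of the reference model.
    """
    _require_positive(dt=dt, m_tot=m_tot, m_ref=m_ref)
    return dt * math.sqrt(m_ref / m_tot)


def mass_for_time_step(m_tot: float, dt_ratio: float) -> float:
    """Total mass that preserves the crash rate when the step grows by ``dt_ratio``.

    Doubling the integration time step (``dt_ratio = 2``), as in hydrogen-
    mass-repartitioned force fields, requires quadrupling the water mass:
    ``m_tot' = m_tot * dt_ratio**2``.
    """
    _require_positive(m_tot=m_tot, dt_ratio=dt_ratio)
    return m_tot * dt_ratio**2


def ideal_diffusion_scaling(d_ref: float, m_ref: float, m_tot: float) -> float:
    """Ideal self-diffusion coefficient after mass rescaling (nm^2/ns).

    From the invariance of Newton's equation under joint time/mass scaling,
    ``D' = D_ref * sqrt(m_ref / m_tot)`` at fixed repartitioning.
    """
    _require_positive(d_ref=d_ref, m_ref=m_ref, m_tot=m_tot)
    return d_ref * math.sqrt(m_ref / m_tot)


def viscosity_scaling(eta_ref: float, m_tot: float, m_ref: float) -> float:
    """Ideal shear viscosity after mass rescaling: ``eta' = eta_ref * sqrt(m_tot/m_ref)``."""
    _require_positive(eta_ref=eta_ref, m_tot=m_tot, m_ref=m_ref)
    return eta_ref * math.sqrt(m_tot / m_ref)


def model_card(masses: WaterModelMasses,
               spec: RepartitionSpec | None = None) -> dict:
    """Machine-readable summary of a water model's masses and provenance."""
    card = {"model": masses.as_dict(),
            "published": masses.published().as_dict()}
    if spec is not None:
        card["construction"] = {
            "m_r_g_per_mol": spec.m_r,
            "m_tot_target_g_per_mol": spec.m_tot_target,
            "reference": spec.reference.as_dict(),
            "mass_scale_factor_sq": spec.scale_factor_sq,
            "viscosity_factor": math.sqrt(spec.scale_factor_sq),
            "equivalent_time_step_fs_at_2fs": equivalent_time_step(
                2.0, masses.m_tot, spec.reference.m_tot),
        }
    return card


_SECTION_RE = re.compile(r"^\s*\[\s*(\w+)\s*\]")


def _is_content(line: str) -> bool:
    stripped = line.split(";", 1)[0].strip()
    return bool(stripped)


def apply_to_topology(topology_text: str, masses: WaterModelMasses,
                      molecule_name: str) -> str:
    """Rewrite the mass column of a 3-site water in a GROMACS TOP/ITP text.

    The ``[moleculetype]`` whose name matches ``molecule_name`` must contain
    an ``[atoms]`` block with exactly three atoms in O, H, H order (the
    positional convention of rigid-water blocks).  Only the mass fields of
    those three atom lines are changed; every other byte of the input is
    preserved.  Applying the same masses twice is a no-op.
    """
    lines = topology_text.splitlines(keepends=True)

    section = None
    current_mol = None
    expecting_mol_name = False
    target_atom_lines: list[int] = []
    in_target_atoms = False

    for i, line in enumerate(lines):
        m = _SECTION_RE.match(line)
        if m:
            section = m.group(1).lower()
            expecting_mol_name = section == "moleculetype"
            in_target_atoms = (section == "atoms"
                               and current_mol == molecule_name)
            continue
        if not _is_content(line):
            continue
        if expecting_mol_name:
            current_mol = line.split(";", 1)[0].split()[0]
            expecting_mol_name = False
            continue
        if in_target_atoms:
            target_atom_lines.append(i)

    if current_mol is None and not target_atom_lines:
        # no moleculetype matched at all
        pass
    if not target_atom_lines:
        raise MissingMoleculeError(
            f"moleculetype {molecule_name!r} with an [atoms] block not found")
    if len(target_atom_lines) != 3:
        raise UnsupportedTopologyError(
            f"moleculetype {molecule_name!r} has {len(target_atom_lines)} "
            "atoms; only 3-site waters are supported")

    new_masses = (masses.m_O, masses.m_H, masses.m_H)
    for idx, new_mass in zip(target_atom_lines, new_masses):
        lines[idx] = _replace_mass_field(lines[idx], new_mass)
    return "".join(lines)


def _replace_mass_field(line: str, new_mass: float) -> str:
    """Replace the 8th whitespace-separated field (mass) of an atom line."""
    body, sep, comment = line.partition(";")
    parts = re.split(r"(\s+)", body)
    fields = [j for j, tok in enumerate(parts) if tok and not tok.isspace()]
    # GROMACS atom line: nr type resnr residue atom cgnr charge mass
    if len(fields) < 8:
        raise UnsupportedTopologyError(
            "atom line has no mass column (need 8 fields): " + line.strip())
    parts[fields[7]] = format(new_mass, ".6g")
    return "".join(parts) + sep + comment
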