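"""Parameter containers for the inhibited-autoxidation reaction network.

All quantities are in SI molar/second units (M, s, M^-1 s^-1).  Reported
tables convert to minutes and nM s^-1 where noted.

The model describes azo-initiated peroxidation of an oxidizable lipid LH
(methyl linoleate) dispersed in a membrane-mimetic pseudo-phase (Triton
X-100 micelles or DMPC large unilamellar vesicles), inhibited by one or
more chain-breaking phenolic antioxidants:

* a constant radical flux R_i feeds lipid-peroxyl radicals LOO*;
* LOO* propagates the chain (H abstraction from LH at k_p, followed by
  near-diffusion-limited O2 addition at k_O2);
* LOO* self-terminates at 2k_t;
* a phenol ArOH traps LOO* by H-atom transfer at k_inh, and the phenoxyl
  radical ArO* either cross-terminates with a second LOO*, couples with
  another phenoxyl to a dimer with recovered trapping-competent hydroxyls,
  self-destructs, or regenerates a stronger co-antioxidant.

Bimolecular reactions confined to the lipid pseudo-phase (phenoxyl-phenoxyl
coupling, phenoxyl self-decay, regeneration) are accelerated relative to
their bulk rate constants because the reactants share the small lipid
volume; this is captured by dividing those rate constants by the lipid
volume fraction (``interface_factor``) of the medium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import AutoxkinWarning

#: propagation rate constants of methyl linoleate in the two media (M^-1 s^-1)
MEDIUM_KP = {"micelle": 36.0, "liposome": 41.0}

#: lipid + surfactant volume fraction of the dispersed pseudo-phase.
#: 8 mM Triton X-100 + 2.74 mM MeLin is about 0.5% v/v; 20.2 mM DMPC +
#: 2.74 mM MeLin is about 1.3% v/v.
MEDIUM_INTERFACE_FACTOR = {"micelle": 0.005, "liposome": 0.013}

#: default LOO* + ArO* cross-termination rate constant for *persistent*
#: phenoxyl radicals (dimer-forming polyphenols, tocopheroxyl in dispersed
#: media).  Persistence is what allows radical-radical coupling and
#: regeneration to compete at sub-micromolar radical concentrations.
PERSISTENT_CROSS_DEFAULT = 1.0e4


@dataclass
class ReactionParameters:
    """Rate constants and mechanistic switches of the kinetic scheme.

    Parameters
    ----------
    k_p : float
        Chain-propagation rate constant LOO* + LH (M^-1 s^-1).  36 for
        methyl linoleate in Triton X-100 micelles, 41 in DMPC liposomes.
    k_O2 : float
        L* + O2 addition rate constant, ~1e9 M^-1 s^-1.
    two_kt : float
        Peroxyl self-termination 2k_t (M^-1 s^-1), i.e. the coefficient of
        the radical-removal rate 2k_t [LOO*]^2.  Not known for these media;
        the default 150 is a calibration chosen so that the simulated
        uninhibited rate at R_i = 4.6 nM/s matches the ~550 nM/s implied by
        the measured retardation factors.
    k_rad_cross : float
        LOO* + ArO* cross-termination (M^-1 s^-1) used for non-persistent
        phenoxyls (default 1e8).  Individual antioxidants may override it.
    two_k_AO : float
        Phenoxyl self-decay 2k_ArO* (M^-1 s^-1, bulk value; scaled by
        1/interface_factor inside the lipid phase).  15 M^-1 s^-1 is the
        tocopheroxyl value measured in cationic micelles.
    k_r : float
        Regeneration rate constant ArO* + co-antioxidant (M^-1 s^-1, bulk;
        scaled by 1/interface_factor).  20 M^-1 s^-1 is the micellar
        tocopherol-regeneration value; 0 disables regeneration.
    k_dim : float
        Phenoxyl-phenoxyl coupling *event* rate constant (M^-1 s^-1, bulk;
        scaled by 1/interface_factor).  Each event consumes two phenoxyls
        and yields one dimer carrying two trapping-competent phenols.  The
        default is a calibration at which coupling outruns
        cross-termination for persistent phenoxyls in the dispersed media
        (it does not in homogeneous solution, where the stilbene behaves
        as an ordinary two-radical trap).
    k_dec : float
        Optional first-order antioxidant decomposition (s^-1), e.g. the
        alkaline instability of stilbene polyphenols.  Individual
        antioxidants may override it.
    include_initiator_O2 : bool
        If True, the O2 consumed while converting initiator radicals to
        peroxyls (rate R_i) is added to the oxygen-uptake ledger.
    """

    k_p: float = 36.0
    k_O2: float = 1.0e9
    two_kt: float = 150.0
    k_rad_cross: float = 1.0e8
    two_k_AO: float = 15.0
    k_r: float = 0.0
    k_dim: float = 3.0e4
    k_dec: float = 0.0
    include_initiator_O2: bool = False

    def __post_init__(self) -> None:
        for name in ("k_p", "k_O2", "two_kt", "k_rad_cross", "two_k_AO",
                     "k_r", "k_dim", "k_dec"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if self.k_O2 < 1.0e3 * self.k_p:
            warnings.warn(
                "k_O2 < 1000 k_p: O2 addition is assumed much faster than "
                "propagation; the lumped-peroxyl approximation may be poor",
                AutoxkinWarning, stacklevel=2)


@dataclass
class AntioxidantSpec:
    """One chain-breaking antioxidant in the reaction roster.

    Parameters
    ----------
    name : str
        Identifier (e.g. ``"PMHC"``, ``"RSV"``).
    conc0 : float
        Initial concentration (M).
    k_inh : float
        Inhibition rate constant for H-atom transfer to LOO* (M^-1 s^-1).
    dimerizes : bool
        If True, the phenoxyl radicals of this compound couple pairwise to
        dimers whose recovered hydroxyl groups are themselves
        trapping-competent.
    dimer_k_inh : float
        Inhibition rate constant of the recovered dimer phenols (M^-1 s^-1).
    cascade_depth : int
        Number of coupling generations instantiated as explicit species.
        Radicals of the deepest generation couple to an inert sink.  Must
        be 0 when ``dimerizes`` is False.
    regenerable : bool
        Marks the tocopherol-like species whose phenoxyl radical can be
        re-reduced by a co-antioxidant at ``k_r``.
    k_cross : float or None
        Per-species override of the LOO* + ArO* cross-termination rate
        constant.  ``None`` resolves to the global ``k_rad_cross`` for
        ordinary phenoxyls, or to :data:`PERSISTENT_CROSS_DEFAULT` for
        dimer-forming (persistent) phenoxyls.
    k_dec : float or None
        Per-species override of the first-order decomposition rate (s^-1).
    """

    name: str
    conc0: float
    k_inh: float
    dimerizes: bool = False
    dimer_k_inh: float = 0.0
    cascade_depth: int = 0
    regenerable: bool = False
    k_cross: float | None = None
    k_dec: float | None = None

    def __post_init__(self) -> None:
        if self.conc0 < 0:
            raise ValueError(f"{self.name}: conc0 must be >= 0")
        if self.k_inh <= 0:
            raise ValueError(f"{self.name}: k_inh must be > 0")
        if self.dimer_k_inh < 0:
            raise ValueError(f"{self.name}: dimer_k_inh must be >= 0")
        if self.cascade_depth < 0:
            raise ValueError(f"{self.name}: cascade_depth must be >= 0")
        if not self.dimerizes and self.cascade_depth != 0:
            raise ValueError(
                f"{self.name}: cascade_depth must be 0 when dimerizes=False")

    def resolved_k_cross(self, params: ReactionParameters) -> float:
        if self.k_cross is not None:
            return self.k_cross
        if self.dimerizes:
            return PERSISTENT_CROSS_DEFAULT
        return params.k_rad_cross

    def resolved_k_dec(self, params: ReactionParameters) -> float:
        return params.k_dec if self.k_dec is None else self.k_dec


@dataclass
class ExperimentSystem:
    """Medium, concentrations and initiation flux for one run.

    Defaults follow the standard protocol: 2.74 mM methyl linoleate in
    8 mM Triton X-100 micelles (or 20.2 mM DMPC liposomes), 10 mM ABAP
    giving an initiation flux of a few nM/s, antioxidants at 1 uM.

    ``pH_label`` is a tag only; it has no mechanistic effect.  ``O2_0`` is
    the initial dissolved O2 of the oxygen-saturated chamber; with
    ``O2_clamped`` (the default) O2 is treated as non-limiting, which is
    adequate for runs consuming <= 10-20% of it.
    """

    medium: str = "micelle"
    pH_label: float = 7.0
    LH0: float = 2.74e-3
    O2_0: float = 1.0e-3
    R_i: float = 4.6e-9
    antioxidants: list[AntioxidantSpec] = field(default_factory=list)
    O2_clamped: bool = True
    interface_factor: float | None = None

    def __post_init__(self) -> None:
        if self.medium not in MEDIUM_INTERFACE_FACTOR:
            raise ValueError(
                f"medium must be one of {sorted(MEDIUM_INTERFACE_FACTOR)}, "
                f"got {self.medium!r}")
        if self.LH0 <= 0:
            raise ValueError("LH0 must be > 0")
        if self.R_i < 0:
            raise ValueError("R_i must be >= 0")
        if not self.O2_clamped and self.O2_0 <= 0:
            raise ValueError("O2_0 must be > 0 when O2 is not clamped")
        names = [a.name for a in self.antioxidants]
        if len(names) != len(set(names)):
            raise ValueError("antioxidant names must be unique")

    @property
    def resolved_interface_factor(self) -> float:
        if self.interface_factor is not None:
            return self.interface_factor
        return MEDIUM_INTERFACE_FACTOR[self.medium]

    def antioxidant(self, name: str) -> AntioxidantSpec:
        for a in self.antioxidants:
            if a.name == name:
                return a
        raise KeyError(f"no antioxidant named {name!r}")
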