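"""Model parameterization and validation.

A single :class:`ModelParams` instance fully determines one simulation run:
lattice geometry, the movement and conversion hypotheses under test, the
genotype, all rate parameters and the RNG seed.  Identical parameters and
seed give bit-identical trajectories.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

MOVEMENT_RULES = ("a", "b", "c", "d")
CONVERSION_RULES = ("i", "ii", "iii", "iv")
GENOTYPES = ("wild_type", "reeler", "dab1", "dab1_conditional")


class ConfigurationError(ValueError):
    """Raised when a parameter value violates its contract.

    The message always names the offending field.
    """


@dataclass
class ModelParams:
    """Full parameterization of one simulation.

    Parameters
    ----------
    width
        Lattice columns, shared by the intermediate zone (IZ) and the
        cortical plate (CP).
    iz_height
        IZ rows.  Row 1 sits at the germinal boundary where agents are
        introduced, row ``iz_height`` is adjacent to the CP side.
    batch_size
        Agents per batch (one batch forms one cortical layer).  Must be an
        exact multiple of ``width`` so completed layers are whole rows.
    n_batches
        Number of successive batches.  Batch 1 forms the oldest layer (VI),
        batch ``n_batches`` the youngest (II).
    p_vertical
        Probability that an attempted move is vertical (up or down);
        horizontal attempts occur with probability ``1 - p_vertical``.
        Conceptually much larger than 0.5 (vertical, radial migration
        dominates); a violation warns but does not error.
    rho_iz
        Constant upward bias in the IZ.  Conditional on a vertical attempt,
        "up" is chosen with probability ``(1 + rho_iz) / 2``.
    rho_cp
        Bias magnitude used by CP movement rules (b), (c) and (d).
    sensing_distance
        Rows from Layer 1 within which rules (c)/(d) apply their bias.
        On the scale of one final layer thickness.
    p_convert
        Active-to-passive conversion probability per conversion offer
        (rules i, ii and the local part of iv).
    p_move
        Motility thinning probability: a drawn agent attempts any move with
        this probability, otherwise the draw is consumed with no action.
        1 in wild-type; the Dab1 variants reduce it (see ``mutant_p_move``).
    movement_rule, conversion_rule
        Hypothesis selectors, ``a``-``d`` and ``i``-``iv``.
    genotype
        One of ``wild_type``, ``reeler``, ``dab1``, ``dab1_conditional``.
    max_steps
        Hard step cap used to detect non-termination.
    seed
        RNG seed.
    periodic_boundaries
        If True, lateral moves wrap around instead of being aborted
        (robustness-check variant; aborting is the default contract).
    reeler_rho_iz
        IZ bias substituted for ``rho_iz`` under the *reeler* genotype
        (loss of Reelin reduces directional polarization in the IZ).
    mutant_p_move
        Motility probability substituted for ``p_move`` under the full
        *Dab1* genotype (slower cell-autonomous migration).
    conditional_p_move
        Motility probability of the final batch under the conditional
        genotype.  Milder than ``mutant_p_move``: Cre-mediated removal of
        Dab1 late in corticogenesis leaves residual protein, so the
        late-born cohort is slowed rather than crippled.
    dab1_as_reeler
        If True, model *Dab1* exactly like *reeler* (blocked signal
        reception) instead of the default reduced-motility reading.
    """

    width: int = 20
    iz_height: int = 60
    batch_size: int = 200
    n_batches: int = 5
    p_vertical: float = 0.95
    rho_iz: float = 0.5
    rho_cp: float = 1.0
    sensing_distance: int = 10
    p_convert: float = 0.015
    p_move: float = 1.0
    movement_rule: str = "b"
    conversion_rule: str = "ii"
    genotype: str = "wild_type"
    max_steps: int = 500_000
    seed: int = 0
    periodic_boundaries: bool = False
    reeler_rho_iz: float = 0.1
    mutant_p_move: float = 0.1
    conditional_p_move: float = 0.7
    dab1_as_reeler: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for name in ("width", "iz_height", "batch_size", "n_batches",
                     "sensing_distance", "max_steps"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("p_vertical", "rho_iz", "rho_cp", "p_convert", "p_move",
                     "reeler_rho_iz", "mutant_p_move", "conditional_p_move"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.batch_size % self.width != 0:
            raise ConfigurationError(
                f"batch_size ({self.batch_size}) must be an exact multiple of "
                f"width ({self.width}) so completed layers are whole rows")
        if self.movement_rule not in MOVEMENT_RULES:
            raise ConfigurationError(
                f"movement_rule must be one of {MOVEMENT_RULES}, got {self.movement_rule!r}")
        if self.conversion_rule not in CONVERSION_RULES:
            raise ConfigurationError(
                f"conversion_rule must be one of {CONVERSION_RULES}, got {self.conversion_rule!r}")
        if self.genotype not in GENOTYPES:
            raise ConfigurationError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.p_vertical <= 1.0 - self.p_vertical:
            warnings.warn(
                "p_vertical <= 0.5: vertical attempts are expected to dominate "
                "horizontal ones (radial migration)", UserWarning, stacklevel=2)

    # -- conveniences ---------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.batch_size * self.n_batches

    @property
    def cp_rows_final(self) -> int:
        """CP height at completion (all agents settled in full rows)."""
        return self.n_agents // self.width

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**d)
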