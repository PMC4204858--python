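"""Genotype parameter transformations and the 16-combination rule matrix.

The movement and conversion hypotheses are formulated for the wild-type
cortex; the Reelin-signalling genotypes are expressed as transformations of
the wild-type parameters:

* ``wild_type`` -- identity.
* ``reeler`` -- no Reelin anywhere: the IZ upward bias drops to a residual
  value, chemotactic CP bias vanishes (rules b-d behave like rule a; rule a
  is unaffected), and the Layer-1 stop signal is inert (rule iii can never
  fire, rule iv degrades to rule ii).
* ``dab1`` -- the Reelin signal is sent but cannot be received; modeled as
  a cell-autonomous reduction of motility with wild-type bias and
  conversion.  The alternative reading (identical to *reeler*) is exposed
  via ``dab1_as_reeler``.
* ``dab1_conditional`` -- Dab1 removed only from late-born neurons: all
  batches are wild-type except the final batch, which carries a milder
  motility reduction (late Cre onset leaves residual Dab1 protein).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ConfigurationError, ModelParams, MOVEMENT_RULES, CONVERSION_RULES


@dataclass(frozen=True)
class GenotypeProfile:
    """Resolved per-genotype behaviour flags and effective rates."""

    genotype: str
    chemotaxis_on: bool
    stop_signal_on: bool
    rho_iz_effective: float
    p_move_effective: float
    #: batch number -> {"p_move": ..., "rho_iz": ...} overrides (only the
    #: final batch for the conditional mutant); empty for other genotypes
    per_batch_overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ResolvedParams:
    """A :class:`ModelParams` merged with its :class:`GenotypeProfile`."""

    base: ModelParams
    profile: GenotypeProfile

    @property
    def p_move_by_batch(self) -> np.ndarray:
        """Motility probability indexed by batch number (index 0 unused)."""
        arr = np.full(self.base.n_batches + 1, self.profile.p_move_effective)
        arr[0] = np.nan
        for b, ov in self.profile.per_batch_overrides.items():
            if "p_move" in ov:
                arr[b] = ov["p_move"]
        return arr

    @property
    def rho_iz_by_batch(self) -> np.ndarray:
        """IZ upward bias indexed by batch number (index 0 unused)."""
        arr = np.full(self.base.n_batches + 1, self.profile.rho_iz_effective)
        arr[0] = np.nan
        for b, ov in self.profile.per_batch_overrides.items():
            if "rho_iz" in ov:
                arr[b] = ov["rho_iz"]
        return arr

    def __getattr__(self, name):
        return getattr(object.__getattribute__(self, "base"), name)


def apply_genotype(params) -> ResolvedParams:
    """Resolve a genotype into effective run parameters.

    Idempotent: passing an already-resolved parameter set returns it
    unchanged.
    """
    if isinstance(params, ResolvedParams):
        return params
    if not isinstance(params, ModelParams):
        raise TypeError(f"expected ModelParams, got {type(params).__name__}")
    g = params.genotype
    if g == "wild_type":
        profile = GenotypeProfile(g, chemotaxis_on=True, stop_signal_on=True,
                                  rho_iz_effective=params.rho_iz,
                                  p_move_effective=params.p_move)
    elif g == "reeler" or (g == "dab1" and params.dab1_as_reeler):
        profile = GenotypeProfile(g, chemotaxis_on=False, stop_signal_on=False,
                                  rho_iz_effective=params.reeler_rho_iz,
                                  p_move_effective=params.p_move)
    elif g == "dab1":
        profile = GenotypeProfile(g, chemotaxis_on=True, stop_signal_on=True,
                                  rho_iz_effective=params.rho_iz,
                                  p_move_effective=params.mutant_p_move)
    elif g == "dab1_conditional":
        profile = GenotypeProfile(
            g, chemotaxis_on=True, stop_signal_on=True,
            rho_iz_effective=params.rho_iz,
            p_move_effective=params.p_move,
            per_batch_overrides={params.n_batches: {
                "p_move": params.conditional_p_move}})
    else:  # pragma: no cover - ModelParams.validate already rejects this
        raise ConfigurationError(f"genotype: unknown value {g!r}")
    return ResolvedParams(base=params, profile=profile)


def enumerate_combinations() -> list[tuple[str, str]]:
    """The 16 (movement_rule, conversion_rule) pairs in Table-layout order.

    Row-major over conversion rows i-iv with movement columns a-d, so the
    first pair is ``("a", "i")``.
    """
    return [(m, c) for c in CONVERSION_RULES for m in MOVEMENT_RULES]
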