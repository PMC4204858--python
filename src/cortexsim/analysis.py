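"""Density profiles, ordering classification, and the phenotype matrix screen.

A completed run is summarized by the per-row batch composition of the
cortical plate and by the mean height of each batch above the plate
bottom.  Layer ordering is scored with Kendall's tau between batch birth
order and mean height: tau near +1 means later-born batches settled higher
(the wild-type "inside-out" pattern), tau near -1 the inverted
"outside-in" pattern of the Reelin-signalling mutants.  The conditional
mutant is called by its characteristic bottom-to-top rank order
(VI, V, IV, II, III): only the late-born, slowed batch is misplaced.

The matrix screen runs every (movement, conversion) pair against the
requested genotypes and compares each cell's outcome to the shipped
expectation fixture.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import kendalltau

from .engine import CompletedSim, run
from .params import ModelParams
from .scenarios import enumerate_combinations

#: the layering pattern each genotype is expected to show
EXPECTED_PHENOTYPE = {
    "wild_type": "inside_out",
    "reeler": "outside_in",
    "dab1": "outside_in",
    "dab1_conditional": "conditional_misplaced",
}

#: bottom-to-top batch order of the conditional-mutant call, for 5 batches:
#: layers VI, V, IV below, then the mutant II below III
_CONDITIONAL_ORDER = (1, 2, 3, 5, 4)


class NonTerminatedRunError(RuntimeError):
    """Raised when a profile is requested for a run that never completed.

    Callers should classify such runs as ``no_layering`` instead.
    """


@dataclass
class DensityProfile:
    """Per-row, per-batch occupancy fractions of the cortical plate.

    ``fractions[h, b]`` is the fraction of sites in row ``h`` (0 = bottom
    of the CP, counting upward toward Layer 1) held by batch ``b + 1``.
    At completion every row is full, so each row sums to one.
    """

    fractions: np.ndarray  # (cp_rows, n_batches)
    n_realizations: int = 1

    @property
    def n_rows(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_batches(self) -> int:
        return self.fractions.shape[1]

    def mean_heights(self) -> np.ndarray:
        """Mean height above the CP bottom for each batch (rows; bottom row = 1)."""
        heights = np.arange(1, self.n_rows + 1, dtype=float)
        mass = self.fractions.sum(axis=0)
        return (heights @ self.fractions) / mass

    def to_frame(self):
        import pandas as pd
        rows, batches = np.meshgrid(np.arange(1, self.n_rows + 1),
                                    np.arange(1, self.n_batches + 1), indexing="ij")
        return pd.DataFrame({
            "row": rows.ravel(), "batch": batches.ravel(),
            "fraction": self.fractions.ravel(),
            "n_realizations": self.n_realizations,
        })


@dataclass
class PhenotypeCall:
    """Ordering classification of one run or one ensemble."""

    call: str                      # inside_out | outside_in | conditional_misplaced
    #                              # | no_layering | other
    ordering_stat: float           # Kendall tau, birth order vs mean height
    mean_heights: np.ndarray
    distinctness: float = float("nan")


def density_profile(completed: CompletedSim) -> DensityProfile:
    """Exact per-row batch fractions from the final lattice of one run."""
    if completed.status != "complete":
        raise NonTerminatedRunError(
            "run did not terminate; classify it as no_layering instead of "
            "profiling it")
    state = completed.state
    p = state.params
    cp = state.cp_view()
    # cp row 0 is adjacent to Layer 1; profile row 0 is the CP bottom
    batch_of = state.batch[cp]          # (cp_rows, width), all sites occupied
    frac = np.zeros((cp.shape[0], p.n_batches))
    for b in range(1, p.n_batches + 1):
        frac[:, b - 1] = (batch_of == b).mean(axis=1)
    return DensityProfile(fractions=frac[::-1].copy(), n_realizations=1)


def mean_heights_of_run(completed: CompletedSim) -> np.ndarray:
    """Per-batch mean height above the CP bottom from the final lattice."""
    state = completed.state
    p = state.params
    cph = state.cp_height
    in_cp = state.comp == 3
    heights = cph - state.arow[in_cp]   # bottom row -> 1, top row -> cph
    batches = state.batch[in_cp]
    out = np.full(p.n_batches, np.nan)
    for b in range(1, p.n_batches + 1):
        sel = batches == b
        if sel.any():
            out[b - 1] = heights[sel].mean()
    return out


def classify(mean_heights: np.ndarray, genotype: str, status: str) -> PhenotypeCall:
    """Turn per-batch mean heights into a phenotype call.

    A non-terminated run is always ``no_layering`` (the agents stay motile
    and well-mixed).  For the conditional mutant the characteristic
    misplaced order is checked before the tau thresholds, because its tau
    (0.8 for five batches) would otherwise be read as inside-out.
    """
    mean_heights = np.asarray(mean_heights, float)
    if status == "non_terminated":
        return PhenotypeCall("no_layering", float("nan"), mean_heights)
    tau = kendalltau(np.arange(1, len(mean_heights) + 1), mean_heights).statistic
    order = tuple(int(b) for b in np.argsort(mean_heights) + 1)
    eps = 1e-9  # tau on 5 points is a ratio of small integers; absorb rounding
    if (genotype == "dab1_conditional"
            and len(mean_heights) == 5 and order == _CONDITIONAL_ORDER):
        call = "conditional_misplaced"
    elif tau >= 0.8 - eps:
        call = "inside_out"
    elif tau <= -0.8 + eps:
        call = "outside_in"
    else:
        call = "other"
    return PhenotypeCall(call, float(tau), mean_heights)


def distinctness(profile: DensityProfile) -> float:
    """How well separated adjacent batches are, in [0, 1].

    One minus the mean overlap coefficient over adjacent batch pairs,
    where the overlap of batches k and k+1 is
    ``sum_rows min(f_k, f_{k+1}) / min(sum f_k, sum f_{k+1})``.
    1 = perfectly disjoint bands, 0 = identical distributions.
    """
    f = profile.fractions
    overlaps = []
    for k in range(profile.n_batches - 1):
        a, b = f[:, k], f[:, k + 1]
        denom = min(a.sum(), b.sum())
        overlaps.append(np.minimum(a, b).sum() / denom if denom > 0 else 1.0)
    return 1.0 - float(np.mean(overlaps))


# ---------------------------------------------------------------------------
# ensembles

@dataclass
class EnsembleResult:
    """Profiles and calls over an ensemble of seeds for one parameter set."""

    params: ModelParams
    profile: DensityProfile | None      # mean over completed members
    calls: list                          # per-run PhenotypeCall
    majority_call: str
    n_realizations: int
    n_non_terminated: int
    seeds: list
    distinctness: float = float("nan")

    @property
    def taus(self) -> np.ndarray:
        return np.array([c.ordering_stat for c in self.calls])


def _majority(calls: list[str]) -> str:
    counts = Counter(calls).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return "other"
    return counts[0][0]


def run_ensemble(params: ModelParams, n_realizations: int, seed_base: int) -> EnsembleResult:
    """Run seeds ``seed_base .. seed_base + n - 1`` and pool the results.

    Non-terminated members are excluded from the averaged profile, counted,
    and classified as ``no_layering``; if every member fails to terminate
    the ensemble call is ``no_layering``.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    seeds = [seed_base + i for i in range(n_realizations)]
    profiles, calls = [], []
    n_bad = 0
    for s in seeds:
        completed = run(params.replace(seed=s))
        if completed.status == "complete":
            prof = density_profile(completed)
            profiles.append(prof.fractions)
            calls.append(classify(mean_heights_of_run(completed),
                                  params.genotype, completed.status))
        else:
            n_bad += 1
            calls.append(classify(np.full(params.n_batches, np.nan),
                                  params.genotype, completed.status))
    if profiles:
        profile = DensityProfile(np.mean(profiles, axis=0), len(profiles))
        dist = distinctness(profile)
    else:
        profile, dist = None, float("nan")
    return EnsembleResult(
        params=params, profile=profile, calls=calls,
        majority_call=_majority([c.call for c in calls]),
        n_realizations=n_realizations, n_non_terminated=n_bad,
        seeds=seeds, distinctness=dist)


def ensemble_average(params: ModelParams, n_realizations: int,
                     seed_base: int) -> DensityProfile:
    """Element-wise mean density profile over an ensemble of seeds."""
    result = run_ensemble(params, n_realizations, seed_base)
    if result.profile is None:
        raise NonTerminatedRunError(
            "every ensemble member hit the step cap; the ensemble call is "
            "no_layering")
    return result.profile


# ---------------------------------------------------------------------------
# the 16-combination screen

def load_fixture() -> dict:
    """The shipped expectation fixture for the 16 x 4 phenotype matrix.

    ``cells["<movement>,<conversion>"][genotype]`` is one of
    ``must_succeed``, ``must_fail`` or ``either``.
    """
    with resources.files("cortexsim.data").joinpath("table1_fixture.json").open() as fh:
        return json.load(fh)


@dataclass
class MatrixCell:
    movement_rule: str
    conversion_rule: str
    genotype: str
    call: str
    tau: float
    distinctness: float
    success: bool            # call matches the genotype's expected phenotype
    verdict: str             # match | mismatch | either-allowed
    n_non_terminated: int


@dataclass
class PhenotypeMatrix:
    """All screened cells plus Table-level summary counts."""

    cells: dict = field(default_factory=dict)   # (move, conv, genotype) -> MatrixCell
    genotypes: list = field(default_factory=list)
    n_realizations: int = 0
    full_success_pairs: list = field(default_factory=list)
    definitive_failure_pairs: list = field(default_factory=list)
    single_failure_pairs: list = field(default_factory=list)

    def cell(self, movement_rule, conversion_rule, genotype) -> MatrixCell:
        return self.cells[(movement_rule, conversion_rule, genotype)]

    def to_records(self) -> list[dict]:
        return [{
            "movement_rule": c.movement_rule, "conversion_rule": c.conversion_rule,
            "genotype": c.genotype, "call": c.call,
            "tau": None if np.isnan(c.tau) else round(c.tau, 4),
            "distinctness": None if np.isnan(c.distinctness) else round(c.distinctness, 4),
            "success": c.success, "verdict": c.verdict,
            "n_non_terminated": c.n_non_terminated,
        } for c in self.cells.values()]


def run_matrix(base_params: ModelParams, genotypes=None, n_realizations: int = 10,
               seed_base: int = 0, fixture: dict | None = None,
               progress=None) -> PhenotypeMatrix:
    """Screen the 16 rule pairs against the requested genotypes.

    Each cell runs an ensemble, takes the majority phenotype call, marks it
    a success if it matches the genotype's expected pattern, and scores it
    against the fixture.  Pair-level summaries (all-phenotype successes,
    >= 2 failures, exactly one failure) are computed only when all four
    genotypes are screened.

    Seeds: the ensemble for cell index ``k`` (in enumeration order) uses
    ``seed_base + 1000 * k`` as its base, keeping members independent.
    """
    if genotypes is None:
        genotypes = list(EXPECTED_PHENOTYPE)
    bad = set(genotypes) - set(EXPECTED_PHENOTYPE)
    if bad:
        raise ValueError(f"unknown genotype(s): {sorted(bad)}")
    if fixture is None:
        fixture = load_fixture()
    matrix = PhenotypeMatrix(genotypes=list(genotypes), n_realizations=n_realizations)
    pairs = enumerate_combinations()
    k = 0
    for move, conv in pairs:
        for g in genotypes:
            params = base_params.replace(movement_rule=move, conversion_rule=conv,
                                         genotype=g)
            res = run_ensemble(params, n_realizations, seed_base + 1000 * k)
            k += 1
            success = res.majority_call == EXPECTED_PHENOTYPE[g]
            expected = fixture["cells"][f"{move},{conv}"][g]
            if expected == "either":
                verdict = "either-allowed"
            elif (expected == "must_succeed") == success:
                verdict = "match"
            else:
                verdict = "mismatch"
            matrix.cells[(move, conv, g)] = MatrixCell(
                movement_rule=move, conversion_rule=conv, genotype=g,
                call=res.majority_call, tau=float(np.nanmean(res.taus))
                if np.isfinite(res.taus).any() else float("nan"),
                distinctness=res.distinctness, success=success, verdict=verdict,
                n_non_terminated=res.n_non_terminated)
            if progress is not None:
                progress(move, conv, g, res.majority_call)
    if set(genotypes) == set(EXPECTED_PHENOTYPE):
        for move, conv in pairs:
            fails = sum(1 for g in genotypes
                        if not matrix.cells[(move, conv, g)].success)
            pair = f"{move},{conv}"
            if fails == 0:
                matrix.full_success_pairs.append(pair)
            elif fails == 1:
                matrix.single_failure_pairs.append(pair)
            else:
                matrix.definitive_failure_pairs.append(pair)
    return matrix
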