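"""Repair-pathway assignment, misrepair, repair kinetics and cell fate.

Every DSB is routed to a repair pathway given the cell's phenotype and cycle
phase: canonical NHEJ handles all breaks in G1 and the simple breaks in
S/G2, complex breaks in S/G2 preferentially route to HR, and alt-EJ acts as
a backup for breaks whose primary pathway is (effectively) defective. A
pathway with the *complex-only* defect fails only for complex breaks, which
is how loss of Artemis or DNA-PKcs is represented.

Misrepair is proximity-driven: break i pairs with break j with Gaussian
weight ``exp(-d_ij^2 / (2 sigma^2))`` against a fixed correct-rejoining
weight, so dense intra-track clustering at high LET directly raises
misrepair. Breaks handled by the error-prone alt-EJ backup carry an
elevated misrepair multiplier and a per-phenotype probability of permanent
failure; knockout lethality is therefore dominated by LET-independent
failure-to-repair channels, while the LET dependence of survival emerges
from break clustering alone.

Cell fate multiplies three survival factors: lethal-aberration escape for
each misrepair event (inter- vs intra-chromosomal), escape from each
unrepaired break, and a G1-checkpoint term ``exp(-g * mu * lesions)`` whose
activity ``g`` runs continuously from 0 (checkpoint-null, e.g. p53-/-) to 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources

import numba
import numpy as np
import yaml

from .foci import FociTimeCourse
from .induction import DSBSet, InductionParams, assign_complexity, count_resolvable_foci, sample_breaks
from .qualities import NucleusGeometry, RadiationQuality
from .survival import DoseResponse

__all__ = [
    "PathwayStatus",
    "CellPhenotype",
    "KineticsParams",
    "RepairOutcome",
    "PHENOTYPE_PRESETS",
    "assign_pathway",
    "misrepair_pairing",
    "simulate_repair_outcome",
    "cell_survival_probability",
    "predict_survival_curve",
    "expected_foci_timecourse",
    "simulate_foci_timecourse",
]

PHASES = ("G1", "S", "G2")


class PathwayStatus(str, enum.Enum):
    """Functional state of a repair pathway in a given genetic background."""

    FUNCTIONAL = "functional"
    DEFECTIVE = "defective"
    COMPLEX_ONLY_DEFECTIVE = "complex_only_defective"


@dataclass(frozen=True)
class CellPhenotype:
    """Simplified radiation phenotype of a cell line.

    Attributes
    ----------
    label : str
        Cell-line name.
    genome_size_gbp : float
        Diploid genome size, Gbp (informational).
    n_chromosomes : int
        Chromosome count; misrepair partners on different chromosomes form
        interchromosomal (more lethal) exchanges.
    nhej, hr, alt_ej : PathwayStatus
        Per-pathway repair status.
    g1_checkpoint_activity : float
        Continuous G1 checkpoint/arrest activity g in [0, 1]; scales the
        per-lesion checkpoint-mediated loss of clonogenicity.
    alt_ej_failure_prob : float
        Probability that a break handed to the alt-EJ backup is never
        rejoined. Per-phenotype because backup capacity has its own genetic
        dependencies (notably ATM-driven resection and signalling).
    nhej_failure_prob, hr_failure_prob : float
        Probability that a break routed to a *functional* NHEJ/HR pathway
        nonetheless fails and falls through to the backup; models partial
        loss of pathway components (e.g. DNA-PKcs on simple breaks, FANCD2
        within HR) independently of break complexity and LET.
    cycle_fractions : dict
        Asynchronous-population fractions for G1/S/G2, summing to 1.
    nhej_rate_scale, hr_rate_scale : float
        Multipliers on the nominal clearance rate of breaks routed to that
        pathway; values < 1 slow focus clearance (repair kinetics) without
        changing repair fidelity.
    """

    label: str
    nhej: PathwayStatus = PathwayStatus.FUNCTIONAL
    hr: PathwayStatus = PathwayStatus.FUNCTIONAL
    alt_ej: PathwayStatus = PathwayStatus.FUNCTIONAL
    g1_checkpoint_activity: float = 1.0
    alt_ej_failure_prob: float = 0.06
    nhej_failure_prob: float = 0.0
    hr_failure_prob: float = 0.0
    genome_size_gbp: float = 6.2
    n_chromosomes: int = 46
    cycle_fractions: dict = field(
        default_factory=lambda: {"G1": 0.6, "S": 0.25, "G2": 0.15}
    )
    nhej_rate_scale: float = 1.0
    hr_rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.g1_checkpoint_activity <= 1.0:
            raise ValueError("g1_checkpoint_activity must lie in [0, 1]")
        for name in ("alt_ej_failure_prob", "nhej_failure_prob", "hr_failure_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(self.cycle_fractions.get(p, 0.0) for p in PHASES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cycle_fractions must sum to 1")
        if self.nhej_rate_scale <= 0 or self.hr_rate_scale <= 0:
            raise ValueError("rate scales must be positive")


@dataclass(frozen=True)
class KineticsParams:
    """Repair-kinetics and cell-fate parameters.

    All values are configurable model parameters, chosen to reproduce the
    qualitative behaviour of repair-proficient and -deficient human cells
    (see the methods note); they are not measured constants.

    Attributes
    ----------
    rate_fast : float
        Canonical-NHEJ clearance rate for simple breaks, h^-1.
    rate_slow : float
        Clearance rate for complex and HR-routed breaks, h^-1.
    rate_backup : float
        alt-EJ backup clearance rate, h^-1.
    sigma_misrepair : float
        Gaussian proximity-kernel scale for misrepair, um.
    w_self : float
        Fixed weight of correct rejoining against the summed misrepair
        weights; calibrated so wild-type X-ray misrepair is a few percent
        of breaks at 2 Gy.
    p_lethal_inter, p_lethal_intra : float
        Lethality of an inter-/intra-chromosomal misrepair event.
    p_lethal_unrepaired : float
        Lethality of each permanently unrepaired break.
    mu_g1 : float
        Per-lesion weight of checkpoint-mediated clonogenic loss.
    p_hr_route : float
        Probability that a complex break in S/G2 is routed to HR.
    alt_ej_misrepair_multiplier : float
        Misrepair-weight multiplier for breaks handled by alt-EJ.
    """

    rate_fast: float = 2.0
    rate_slow: float = 0.2
    rate_backup: float = 0.1
    sigma_misrepair: float = 0.35
    w_self: float = 9.5
    p_lethal_inter: float = 0.5
    p_lethal_intra: float = 0.1
    p_lethal_unrepaired: float = 0.8
    mu_g1: float = 0.1
    p_hr_route: float = 0.8
    alt_ej_misrepair_multiplier: float = 1.5

    def __post_init__(self) -> None:
        for name in ("rate_fast", "rate_slow", "rate_backup", "sigma_misrepair",
                     "w_self", "alt_ej_misrepair_multiplier"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_lethal_inter", "p_lethal_intra", "p_lethal_unrepaired",
                     "p_hr_route"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mu_g1 < 0:
            raise ValueError("mu_g1 must be non-negative")


# per-break outcome codes
CORRECT, MISREPAIRED, UNREPAIRED = 0, 1, 2
# pathway codes
PW_NHEJ, PW_HR, PW_ALTEJ, PW_NONE = 0, 1, 2, 3
PATHWAY_LABELS = ("nhej", "hr", "alt_ej", "none")


@dataclass(frozen=True)
class RepairOutcome:
    """Outcome of repair for one nucleus.

    Per-break arrays run parallel to the originating :class:`DSBSet`;
    ``partner[i]`` is the misrepair partner index or -1, ``rates[i]`` the
    clearance rate (h^-1, inf for instantaneous absence of breaks, nan for
    unrepaired breaks).
    """

    n_correct: int
    n_misrepaired: int
    n_unrepaired: int
    n_inter_events: int
    n_intra_events: int
    labels: np.ndarray
    pathways: np.ndarray
    partner: np.ndarray
    rates: np.ndarray
    phase: str

    @property
    def n_total(self) -> int:
        return self.n_correct + self.n_misrepaired + self.n_unrepaired

    @property
    def n_interchromosomal_misrepair(self) -> int:
        return self.n_inter_events


def _load_phenotype_presets() -> dict[str, CellPhenotype]:
    text = resources.files("letrbe").joinpath("data/phenotypes.yaml").read_text()
    raw = yaml.safe_load(text)
    presets: dict[str, CellPhenotype] = {}
    for label, fields in raw.items():
        fields = dict(fields or {})
        for key in ("nhej", "hr", "alt_ej"):
            if key in fields:
                try:
                    fields[key] = PathwayStatus(fields[key])
                except ValueError as exc:
                    raise ValueError(
                        f"phenotype {label!r}: invalid {key} status {fields[key]!r}"
                    ) from exc
        unknown = set(fields) - {
            "nhej", "hr", "alt_ej", "g1_checkpoint_activity", "alt_ej_failure_prob",
            "nhej_failure_prob", "hr_failure_prob",
            "genome_size_gbp", "n_chromosomes", "cycle_fractions",
            "nhej_rate_scale", "hr_rate_scale",
        }
        if unknown:
            raise ValueError(f"phenotype {label!r}: unknown fields {sorted(unknown)}")
        presets[label] = CellPhenotype(label=label, **fields)
    return presets


#: The eight study cell lines, keyed by label.
PHENOTYPE_PRESETS: dict[str, CellPhenotype] = _load_phenotype_presets()

#: Preset labels in the expected order of increasing X-ray MID
#: (most sensitive first).
SENSITIVITY_ORDER: tuple[str, ...] = (
    "atm", "lig4", "dnapk", "artemis", "brca1", "fancd2", "wild_type", "p53",
)


def _resolve_status(status: PathwayStatus, is_complex: bool) -> PathwayStatus:
    if status is PathwayStatus.COMPLEX_ONLY_DEFECTIVE:
        return PathwayStatus.DEFECTIVE if is_complex else PathwayStatus.FUNCTIONAL
    return status


def assign_pathway(
    is_complex: bool,
    phenotype: CellPhenotype,
    phase: str,
    params: KineticsParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, PathwayStatus]:
    """Route a single break to its repair pathway.

    In G1 the primary pathway is NHEJ for every break; in S/G2 a complex
    break routes to HR with probability ``p_hr_route`` (drawn from ``rng``,
    deterministic HR routing if no generator is given), simple breaks to
    NHEJ. A break whose primary pathway is effectively defective (the
    complex-only defect counts only for complex breaks) falls through to
    the alt-EJ backup; if alt-EJ is itself (effectively) defective the
    break is unrepairable and ``("none", DEFECTIVE)`` is returned.

    Returns
    -------
    (pathway_label, effective_status)
    """
    if phase not in PHASES:
        raise ValueError(f"unknown cell-cycle phase {phase!r}")
    params = params or KineticsParams()

    if phase == "G1" or not is_complex:
        primary, status = "nhej", phenotype.nhej
    else:
        route_to_hr = True if rng is None else bool(rng.random() < params.p_hr_route)
        primary, status = ("hr", phenotype.hr) if route_to_hr else ("nhej", phenotype.nhej)

    eff = _resolve_status(status, is_complex)
    if eff is PathwayStatus.FUNCTIONAL:
        return primary, eff
    eff_alt = _resolve_status(phenotype.alt_ej, is_complex)
    if eff_alt is PathwayStatus.FUNCTIONAL:
        return "alt_ej", eff_alt
    return "none", PathwayStatus.DEFECTIVE


def misrepair_pairing(
    positions: np.ndarray,
    params: KineticsParams,
    rng: np.random.Generator,
    multipliers: np.ndarray | None = None,
    eligible: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy sequential misrepair pairing with reciprocal commitment.

    For break i the weight against break j is
    ``w_ij = sqrt(m_i m_j) * exp(-d_ij^2 / (2 sigma^2))`` with per-break
    misrepair multipliers ``m``; correct rejoining carries the fixed weight
    ``w_self``. Breaks are visited in index order; an unresolved break i
    misrepairs with probability ``S_i / (w_self + S_i)`` where ``S_i`` sums
    the weights to still-available partners, draws its partner
    proportionally to ``w_ij``, and both ends commit. Ineligible breaks
    (e.g. permanently unrepaired ones) neither misrepair nor serve as
    partners.

    A precomputed Gaussian ``kernel`` matrix may be supplied to avoid
    recomputing distances when the same geometry is paired repeatedly.

    Returns the partner index array (-1 for no misrepair).
    """
    n = len(positions)
    partner = np.full(n, -1, dtype=np.int64)
    if n < 2:
        return partner
    if eligible is None:
        eligible = np.ones(n, dtype=bool)

    if kernel is None:
        kernel = _proximity_kernel(positions, params.sigma_misrepair)
    if multipliers is None:
        weights = kernel  # unit multipliers: the kernel is the weight matrix
    else:
        root_m = np.sqrt(multipliers)
        weights = kernel * np.outer(root_m, root_m)

    # a fixed pair of uniforms per break (accept, partner), drawn up front:
    # the draw count is independent of the outcomes, so simulations that
    # share a seed stay aligned across qualities and phenotypes
    u_accept = rng.random(n)
    u_partner = rng.random(n)
    return _greedy_pairing_core(
        weights, u_accept, u_partner,
        np.ascontiguousarray(eligible, dtype=bool), params.w_self,
    )


def _proximity_kernel(positions: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian proximity weights with a zeroed diagonal (no self-pairing)."""
    gram = positions @ positions.T
    sq = np.einsum("ij,ij->i", positions, positions)
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    kernel = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(kernel, 0.0)
    return kernel


@numba.njit(cache=False)
def _greedy_pairing_core(weights, u_accept, u_partner, eligible, w_self):  # pragma: no cover
    n = weights.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    resolved = np.zeros(n, dtype=numba.boolean)
    available = eligible.copy()
    for i in range(n):
        if resolved[i] or not eligible[i]:
            continue
        available[i] = False
        total = 0.0
        for j in range(n):
            if available[j]:
                total += weights[i, j]
        if total > 0.0 and u_accept[i] < total / (w_self + total):
            target = u_partner[i] * total
            jsel = -1
            acc = 0.0
            for j in range(n):
                if available[j]:
                    acc += weights[i, j]
                    if acc > target:
                        jsel = j
                        break
            if jsel < 0:
                for j in range(n - 1, -1, -1):
                    if available[j]:
                        jsel = j
                        break
            partner[i] = jsel
            partner[jsel] = i
            resolved[jsel] = True
            available[jsel] = False
        resolved[i] = True
    return partner


def _draw_phase(phenotype: CellPhenotype, rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for phase in PHASES:
        acc += phenotype.cycle_fractions.get(phase, 0.0)
        if u < acc:
            return phase
    return PHASES[-1]


def simulate_repair_outcome(
    dsbs: DSBSet,
    phenotype: CellPhenotype,
    params: KineticsParams,
    rng: np.random.Generator,
    phase: str | None = None,
    kernel: np.ndarray | None = None,
) -> RepairOutcome:
    """Simulate repair, misrepair and failure outcomes for one nucleus.

    Routing follows :func:`assign_pathway` (vectorised). Breaks that fall
    through to a functional alt-EJ backup fail permanently with the
    phenotype's ``alt_ej_failure_prob`` and otherwise resolve at the backup
    rate with an elevated misrepair multiplier. Breaks routed to a slowed
    primary pathway carry multiplier ``nominal_rate / actual_rate``.
    Misrepair pairing runs over all resolving breaks; misrepair events are
    labelled inter- or intra-chromosomal from the partners' chromosome ids.
    """
    n = len(dsbs)
    if phase is None:
        phase = _draw_phase(phenotype, rng)
    if phase not in PHASES:
        raise ValueError(f"unknown cell-cycle phase {phase!r}")
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return RepairOutcome(0, 0, 0, 0, 0, empty, empty, empty,
                             np.empty(0), phase)

    # routing and failure uniforms are drawn for every break regardless of
    # whether they are used, keeping the draw count fixed (CRN alignment)
    route_draws = rng.random(n)
    primary_failure_draws = rng.random(n)
    failure_draws = rng.random(n)

    is_complex = dsbs.is_complex
    pathways = np.full(n, PW_NHEJ, dtype=np.int64)
    if phase != "G1":
        hr_mask = is_complex & (route_draws < params.p_hr_route)
        pathways[hr_mask] = PW_HR

    def effective_defective(status: PathwayStatus, mask: np.ndarray) -> np.ndarray:
        if status is PathwayStatus.DEFECTIVE:
            return mask
        if status is PathwayStatus.COMPLEX_ONLY_DEFECTIVE:
            return mask & is_complex
        return np.zeros(n, dtype=bool)

    fell_through = (
        effective_defective(phenotype.nhej, pathways == PW_NHEJ)
        | effective_defective(phenotype.hr, pathways == PW_HR)
        # stochastic failure of an otherwise functional primary pathway
        | ((pathways == PW_NHEJ) & (primary_failure_draws < phenotype.nhej_failure_prob))
        | ((pathways == PW_HR) & (primary_failure_draws < phenotype.hr_failure_prob))
    )
    alt_dead = effective_defective(phenotype.alt_ej, fell_through)
    pathways[fell_through] = PW_ALTEJ
    pathways[alt_dead] = PW_NONE

    labels = np.full(n, CORRECT, dtype=np.int64)
    labels[alt_dead] = UNREPAIRED
    failures = (pathways == PW_ALTEJ) & (failure_draws < phenotype.alt_ej_failure_prob)
    labels[failures] = UNREPAIRED

    # clearance rates (focus kinetics): fast for simple NHEJ, slow for
    # complex/HR-routed breaks, backup rate for alt-EJ; phenotype rate
    # scales slow clearance without changing fidelity
    nominal = np.where(is_complex, params.rate_slow, params.rate_fast)
    nominal[pathways == PW_HR] = params.rate_slow
    rates = nominal.copy()
    rates[pathways == PW_NHEJ] = nominal[pathways == PW_NHEJ] * phenotype.nhej_rate_scale
    rates[pathways == PW_HR] = nominal[pathways == PW_HR] * phenotype.hr_rate_scale
    rates[pathways == PW_ALTEJ] = params.rate_backup

    # the error-prone alt-EJ backup carries an elevated misrepair weight
    if np.any(pathways == PW_ALTEJ):
        multipliers = np.ones(n)
        multipliers[pathways == PW_ALTEJ] = params.alt_ej_misrepair_multiplier
    else:
        multipliers = None

    resolving = labels != UNREPAIRED
    partner = misrepair_pairing(
        dsbs.positions, params, rng,
        multipliers=multipliers, eligible=resolving, kernel=kernel,
    )
    labels[partner >= 0] = MISREPAIRED
    rates = np.where(labels == UNREPAIRED, np.nan, rates)

    pairs = np.flatnonzero((partner >= 0) & (np.arange(n) < partner))
    inter = int(
        (dsbs.chromosome_ids[pairs] != dsbs.chromosome_ids[partner[pairs]]).sum()
    )
    intra = len(pairs) - inter

    return RepairOutcome(
        n_correct=int((labels == CORRECT).sum()),
        n_misrepaired=int((labels == MISREPAIRED).sum()),
        n_unrepaired=int((labels == UNREPAIRED).sum()),
        n_inter_events=inter,
        n_intra_events=intra,
        labels=labels,
        pathways=pathways,
        partner=partner,
        rates=rates,
        phase=phase,
    )


def cell_survival_probability(
    outcome: RepairOutcome,
    phenotype: CellPhenotype,
    params: KineticsParams,
) -> float:
    """Clonogenic survival probability given a repair outcome.

    ``P = P_aberration * P_unrepaired * P_checkpoint`` with

    * ``P_aberration = (1-p_inter)^n_inter * (1-p_intra)^n_intra`` over
      misrepair events,
    * ``P_unrepaired = (1-p_unrep)^n_unrepaired``,
    * ``P_checkpoint = exp(-g * mu * (n_misrepaired + n_unrepaired))``.
    """
    p_ab = (
        (1.0 - params.p_lethal_inter) ** outcome.n_inter_events
        * (1.0 - params.p_lethal_intra) ** outcome.n_intra_events
    )
    p_unrep = (1.0 - params.p_lethal_unrepaired) ** outcome.n_unrepaired
    lesions = outcome.n_misrepaired + outcome.n_unrepaired
    p_chk = np.exp(-phenotype.g1_checkpoint_activity * params.mu_g1 * lesions)
    return float(p_ab * p_unrep * p_chk)


def _cell_rngs(seed: int, dose_index: int, cell_index: int):
    """Geometry and repair generators for one simulated nucleus.

    Both are seeded per (dose, cell) but not per quality or phenotype.
    Together with the fixed per-stage draw counts in
    :func:`simulate_repair_outcome` this gives common random numbers:
    curves for different qualities or phenotypes at the same seed share
    their break-count, complexity, routing and pairing randomness, so MID
    ratios (RBE, SER) isolate the physical differences rather than MC
    noise. The geometry stream's first draw is the Poisson break count,
    which is therefore identical across qualities at equal dose.
    """
    geom_rng = np.random.default_rng(np.random.SeedSequence([seed, 2, dose_index, cell_index]))
    repair_rng = np.random.default_rng(np.random.SeedSequence([seed, 3, dose_index, cell_index]))
    return geom_rng, repair_rng


def predict_survival_curve(
    phenotype: CellPhenotype,
    quality: RadiationQuality,
    doses,
    n_cells: int = 1000,
    *,
    geom: NucleusGeometry | None = None,
    induction: InductionParams | None = None,
    kinetics: KineticsParams | None = None,
    seed: int = 0,
    n_repair_reps: int = 8,
) -> DoseResponse:
    """Mechanistic clonogenic survival curve: MC mean over ``n_cells`` nuclei.

    For each dose and nucleus the cycle phase is drawn from the phenotype's
    cycle fractions, breaks are sampled and flagged for complexity, repair
    is simulated and the survival probability evaluated; the per-dose mean
    and MC standard error are returned. ``SF(0) = 1`` exactly.

    Two variance-reduction devices sharpen curve comparisons without
    changing the estimated expectation: nuclei are seeded per (dose, cell)
    independent of quality and phenotype, so curves computed with the same
    seed share break-count, complexity, routing and pairing randomness
    (common random numbers); and the stochastic repair stage is replayed
    ``n_repair_reps`` times on each sampled geometry, averaging the
    survival probability over pairing realisations.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose list")
    if doses[0] != 0:
        doses = np.concatenate(([0.0], doses))
    if n_cells < 100:
        raise ValueError("n_cells must be at least 100 for a stable MC mean")
    geom = geom or NucleusGeometry()
    induction = induction or InductionParams()
    kinetics = kinetics or KineticsParams()

    sf_mean = np.empty(len(doses))
    sf_err = np.empty(len(doses))
    for i, dose in enumerate(doses):
        if dose == 0:
            sf_mean[i], sf_err[i] = 1.0, 0.0
            continue
        probs = np.empty(n_cells)
        for j in range(n_cells):
            geom_rng, _ = _cell_rngs(seed, i, j)
            dsbs = sample_breaks(dose, quality, geom, induction, geom_rng)
            kernel = (
                _proximity_kernel(dsbs.positions, kinetics.sigma_misrepair)
                if len(dsbs) > 1 else None
            )
            acc = 0.0
            for r in range(n_repair_reps):
                repair_rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 3, i, j, r])
                )
                phase = _draw_phase(phenotype, repair_rng)
                flagged = assign_complexity(dsbs, induction.complex_fraction, repair_rng)
                outcome = simulate_repair_outcome(
                    flagged, phenotype, kinetics, repair_rng, phase=phase, kernel=kernel
                )
                acc += cell_survival_probability(outcome, phenotype, kinetics)
            probs[j] = acc / n_repair_reps
        sf_mean[i] = probs.mean()
        sf_err[i] = probs.std(ddof=1) / np.sqrt(n_cells)
    sf_mean = np.maximum(sf_mean, 1e-12)  # DoseResponse requires SF > 0
    return DoseResponse(doses=doses, sf_mean=sf_mean, sf_err=sf_err)


def _clearance_times(
    outcome: RepairOutcome, rng: np.random.Generator
) -> np.ndarray:
    """Per-break focus-clearance times (h); inf for persistent breaks.

    Correctly rejoining breaks clear with exponential waiting times at
    their pathway rate. Unrepaired breaks persist; so do misrepaired
    breaks, whose rearranged joints remain marked as residual damage foci.
    """
    n = outcome.n_total
    u = rng.random(n)  # fixed draw count for CRN alignment
    times = np.full(n, np.inf)
    clearing = outcome.labels == CORRECT
    times[clearing] = -np.log(u[clearing]) / outcome.rates[clearing]
    return times


def expected_foci_timecourse(
    dsbs: DSBSet,
    phenotype: CellPhenotype,
    params: KineticsParams,
    times,
    *,
    resolution: float = 0.5,
    n_reps: int = 50,
    rng: np.random.Generator | None = None,
    phase: str | None = None,
) -> FociTimeCourse:
    """Expected resolvable-focus time course for a fixed break set.

    Repair and clearance are re-simulated ``n_reps`` times; at each
    requested time the surviving (uncleared) breaks are clustered at the
    optical resolution and counted. Returns the mean course with its MC
    standard error as SEM.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    rng = rng if rng is not None else np.random.default_rng()

    counts = np.empty((n_reps, len(times)))
    for r in range(n_reps):
        outcome = simulate_repair_outcome(dsbs, phenotype, params, rng, phase=phase)
        clear = _clearance_times(outcome, rng)
        for k, t in enumerate(times):
            alive = clear > t
            counts[r, k] = count_resolvable_foci(dsbs.positions[alive], resolution)
    sem = counts.std(axis=0, ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.zeros(len(times))
    return FociTimeCourse(
        times=times, mean_foci=counts.mean(axis=0), sem=sem,
        dose=dsbs.dose, quality_label=dsbs.quality.label, cell_line=phenotype.label,
    )


def simulate_foci_timecourse(
    phenotype: CellPhenotype,
    quality: RadiationQuality,
    dose: float,
    times,
    n_nuclei: int = 500,
    *,
    geom: NucleusGeometry | None = None,
    induction: InductionParams | None = None,
    kinetics: KineticsParams | None = None,
    resolution: float = 0.5,
    seed: int = 0,
) -> FociTimeCourse:
    """Population-mean focus kinetics: one fresh nucleus per MC repetition.

    Unlike :func:`expected_foci_timecourse` this resamples the break set
    per nucleus, emulating a per-cell focus count experiment over an
    asynchronous population.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-empty, non-negative, strictly increasing")
    geom = geom or NucleusGeometry()
    induction = induction or InductionParams()
    kinetics = kinetics or KineticsParams()

    counts = np.empty((n_nuclei, len(times)))
    for j in range(n_nuclei):
        geom_rng, repair_rng = _cell_rngs(seed, 0, j)
        phase = _draw_phase(phenotype, repair_rng)
        dsbs = sample_breaks(dose, quality, geom, induction, geom_rng)
        dsbs = assign_complexity(dsbs, induction.complex_fraction, repair_rng)
        outcome = simulate_repair_outcome(dsbs, phenotype, kinetics, repair_rng, phase=phase)
        clear = _clearance_times(outcome, repair_rng)
        for k, t in enumerate(times):
            counts[j, k] = count_resolvable_foci(dsbs.positions[clear > t], resolution)
    sem = counts.std(axis=0, ddof=1) / np.sqrt(n_nuclei)
    return FociTimeCourse(
        times=times, mean_foci=counts.mean(axis=0), sem=sem,
        dose=dose, quality_label=quality.label, cell_line=phenotype.label,
    )
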