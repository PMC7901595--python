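"""Synthetic concordance studies: design generation, generative simulation,
and reconstruction of item-level data from published marginal counts.

Three entry points:

* :func:`generate_design` — a factorial study layout (raters with career
  levels, cases with subspecialty/specimen/lesion attributes, conditional
  question eligibility) from configurable composition counts.
* :func:`simulate_responses` — Bernoulli error outcomes from additive
  logit effects (the same varying-intercepts structure the inference model
  assumes), with completely-at-random missingness.
* :func:`reconstruct_from_marginals` — a seeded combinatorial search for an
  item-level dataset whose five marginal error tables match a published
  count table exactly.  The assignment is non-unique; any dataset passing
  validation is equally compatible with the published marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections.abc import Sequence

import numpy as np
from scipy.special import expit

from .data_model import (
    CATEGORIES,
    LEVELS,
    SPECIMENS,
    SUBSPECIALTIES,
    CaseRecord,
    GroupErrorTable,
    Participant,
    ResponseItem,
    StudyDesign,
    ValidationError,
)

__all__ = [
    "DesignConfig",
    "GenerativeParams",
    "generate_design",
    "table1_design",
    "simulate_responses",
    "reconstruct_from_marginals",
    "table1_items",
]

#: Default answered-question eligibility: the screening question (1) and the
#: free-text diagnosis (3) on all 25 cases, benign/malignant (2) on 16 of the
#: 17 neoplastic cases, histotype (4) on all 10 malignant cases, grade (5) on
#: 9 of them — 85 questions per rater, the only arithmetic consistent with
#: the study's printed totals.
DEFAULT_ELIGIBILITY = {1: 25, 2: 16, 3: 25, 4: 10, 5: 9}

DEFAULT_MISSING_RATE = 100 / 1445


@dataclass(frozen=True)
class DesignConfig:
    """Composition counts for a synthetic study; defaults emulate the study."""

    n_per_level: dict[str, int] = field(
        default_factory=lambda: {"resident": 4, "junior": 6, "expert": 5, "senior": 2}
    )
    n_per_subspecialty: dict[str, int] = field(
        default_factory=lambda: {"breast": 10, "urology": 5, "gastrointestinal": 10}
    )
    n_per_specimen: dict[str, int] = field(
        default_factory=lambda: {"biopsy": 14, "surgery": 11}
    )
    n_per_lesion: dict[str, int] = field(
        default_factory=lambda: {"nontumoral": 8, "benign": 7, "malignant": 10}
    )
    grade_split: tuple[int, int] = (5, 5)  # malignant cases of grade 2 / grade 3
    eligibility_counts: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_ELIGIBILITY)
    )
    missing_rate: float = DEFAULT_MISSING_RATE
    seed: int = 0

    @property
    def n_participants(self) -> int:
        return sum(self.n_per_level.values())

    @property
    def n_cases(self) -> int:
        return sum(self.n_per_subspecialty.values())

    @property
    def n_questions_per_participant(self) -> int:
        return sum(self.eligibility_counts.values())

    def validate(self) -> None:
        if set(self.n_per_level) - set(LEVELS):
            raise ValidationError(f"unknown levels {set(self.n_per_level) - set(LEVELS)}")
        n_cases = self.n_cases
        if sum(self.n_per_specimen.values()) != n_cases:
            raise ValidationError("specimen counts must sum to the number of cases")
        if sum(self.n_per_lesion.values()) != n_cases:
            raise ValidationError("lesion-class counts must sum to the number of cases")
        if sum(self.grade_split) != self.n_per_lesion.get("malignant", 0):
            raise ValidationError("grade split must sum to the number of malignant cases")
        ec = self.eligibility_counts
        n_mal = self.n_per_lesion.get("malignant", 0)
        n_tum = n_mal + self.n_per_lesion.get("benign", 0)
        if ec.get(1) != n_cases or ec.get(3) != n_cases:
            raise ValidationError("categories 1 and 3 must be eligible on every case")
        if ec.get(2, 0) > n_tum:
            raise ValidationError(
                f"category 2 eligible on {ec.get(2)} cases but only {n_tum} are neoplastic"
            )
        for q in (4, 5):
            if ec.get(q, 0) > n_mal:
                raise ValidationError(
                    f"category {q} eligible on {ec.get(q)} cases but only {n_mal} are malignant"
                )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must be in [0, 1]")


@dataclass(frozen=True)
class GenerativeParams:
    """Known-truth parameters for generative simulation, on the logit scale.

    Each optional vector fixes the corresponding cluster effects; when left
    ``None`` the effects are drawn once per study from their population
    distribution (rater intercepts around ``alpha_bar`` with SD
    ``sigma_alpha``; the zero-centred clusters around 0 with their SDs).
    """

    alpha_bar: float = -2.35
    sigma_alpha: float = 0.5
    sigma_beta: float = 0.5
    sigma_gamma: float = 0.5
    sigma_delta: float = 0.5
    sigma_epsilon: float = 0.5
    alpha: tuple[float, ...] | None = None
    beta: tuple[float, ...] | None = None
    gamma: tuple[float, ...] | None = None
    delta: tuple[float, ...] | None = None
    epsilon: tuple[float, ...] | None = None

    def validate(self) -> None:
        for name in ("sigma_alpha", "sigma_beta", "sigma_gamma", "sigma_delta", "sigma_epsilon"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not np.isfinite(self.alpha_bar):
            raise ValidationError("alpha_bar must be finite")


# ---------------------------------------------------------------------------
# Design generation


def generate_design(config: DesignConfig | None = None) -> StudyDesign:
    """Build a factorial study design satisfying all composition marginals.

    Case attributes are paired by seeded shuffles (any crossing satisfies
    the marginal counts); eligibility is assigned respecting the
    lesion-class constraints.  Deterministic given ``config.seed``.
    """
    config = config or DesignConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    participants = []
    i = 1
    for level in LEVELS:
        for _ in range(config.n_per_level.get(level, 0)):
            participants.append(Participant(id=f"P{i}", career_level=level))
            i += 1

    subsp = [s for s in SUBSPECIALTIES for _ in range(config.n_per_subspecialty.get(s, 0))]
    spec = [s for s in SPECIMENS for _ in range(config.n_per_specimen.get(s, 0))]
    lesion = [l for l in ("nontumoral", "benign", "malignant")
              for _ in range(config.n_per_lesion.get(l, 0))]
    rng.shuffle(spec)
    rng.shuffle(lesion)

    n_cases = config.n_cases
    tumoral_idx = [i for i in range(n_cases) if lesion[i] != "nontumoral"]
    malignant_idx = [i for i in range(n_cases) if lesion[i] == "malignant"]
    ec = config.eligibility_counts
    with_q2 = set(rng.choice(tumoral_idx, size=ec.get(2, 0), replace=False).tolist())
    with_q4 = set(rng.choice(malignant_idx, size=ec.get(4, 0), replace=False).tolist())
    with_q5 = set(rng.choice(malignant_idx, size=ec.get(5, 0), replace=False).tolist())

    grades = [2] * config.grade_split[0] + [3] * config.grade_split[1]
    rng.shuffle(grades)
    grade_iter = iter(grades)

    cases = []
    for i in range(n_cases):
        cats = {1, 3}
        if i in with_q2:
            cats.add(2)
        if i in with_q4:
            cats.add(4)
        if i in with_q5:
            cats.add(5)
        cases.append(
            CaseRecord(
                id=i + 1,
                subspecialty=subsp[i],
                specimen=spec[i],
                lesion_class=lesion[i],
                grade=next(grade_iter) if lesion[i] == "malignant" else None,
                eligible_categories=frozenset(cats),
            )
        )
    return StudyDesign(participants=tuple(participants), cases=tuple(cases))


# One concrete 25-case layout whose eligibility structure can carry the
# published marginal counts (the per-case eligibility of the real study is
# not printed; this is a verified-feasible choice, not the study's own).
# Tuples: (subspecialty, specimen, lesion_class, has_q2, has_q4, has_q5)
_TABLE1_CASES = [
    # urology: 2 malignant surgical, 1 malignant biopsy w/o grade, 1 benign, 1 nontumoral
    ("urology", "surgery", "malignant", True, True, True),
    ("urology", "surgery", "malignant", True, True, True),
    ("urology", "biopsy", "malignant", True, True, False),
    ("urology", "biopsy", "benign", True, False, False),
    ("urology", "biopsy", "nontumoral", False, False, False),
    # breast: 4 malignant (1 biopsy), 3 benign (2 biopsy), 3 nontumoral biopsies
    ("breast", "biopsy", "malignant", True, True, True),
    ("breast", "surgery", "malignant", True, True, True),
    ("breast", "surgery", "malignant", True, True, True),
    ("breast", "surgery", "malignant", True, True, True),
    ("breast", "biopsy", "benign", True, False, False),
    ("breast", "biopsy", "benign", True, False, False),
    ("breast", "surgery", "benign", True, False, False),
    ("breast", "biopsy", "nontumoral", False, False, False),
    ("breast", "biopsy", "nontumoral", False, False, False),
    ("breast", "biopsy", "nontumoral", False, False, False),
    # gastrointestinal: 3 malignant (1 biopsy), 3 benign (one without q2), 4 nontumoral
    ("gastrointestinal", "biopsy", "malignant", True, True, True),
    ("gastrointestinal", "surgery", "malignant", True, True, True),
    ("gastrointestinal", "surgery", "malignant", True, True, True),
    ("gastrointestinal", "biopsy", "benign", True, False, False),
    ("gastrointestinal", "surgery", "benign", True, False, False),
    ("gastrointestinal", "surgery", "benign", False, False, False),
    ("gastrointestinal", "biopsy", "nontumoral", False, False, False),
    ("gastrointestinal", "biopsy", "nontumoral", False, False, False),
    ("gastrointestinal", "biopsy", "nontumoral", False, False, False),
    ("gastrointestinal", "surgery", "nontumoral", False, False, False),
]

# Career levels by rater id: one of the four assignments compatible with the
# published per-rater and per-level counts (found by exhaustive search; the
# true assignment is not printed).
_TABLE1_LEVELS = {
    "P1": "junior", "P2": "expert", "P3": "senior", "P4": "junior",
    "P5": "junior", "P6": "senior", "P7": "junior", "P8": "expert",
    "P9": "expert", "P10": "resident", "P11": "resident", "P12": "expert",
    "P13": "resident", "P14": "resident", "P15": "expert", "P16": "junior",
    "P17": "junior",
}


def table1_design() -> StudyDesign:
    """The canonical design used to reconstruct the published item table."""
    participants = tuple(
        Participant(id=f"P{i}", career_level=_TABLE1_LEVELS[f"P{i}"]) for i in range(1, 18)
    )
    grade_cycle = iter([2, 3] * 5)
    cases = []
    for i, (subsp, spec, lesion, q2, q4, q5) in enumerate(_TABLE1_CASES, start=1):
        cats = {1, 3} | ({2} if q2 else set()) | ({4} if q4 else set()) | ({5} if q5 else set())
        cases.append(
            CaseRecord(
                id=i,
                subspecialty=subsp,
                specimen=spec,
                lesion_class=lesion,
                grade=next(grade_cycle) if lesion == "malignant" else None,
                eligible_categories=frozenset(cats),
            )
        )
    return StudyDesign(participants=participants, cases=tuple(cases))


# ---------------------------------------------------------------------------
# Generative simulation


def _design_indices(design: StudyDesign):
    """Integer-coded label arrays over the design's eligible triples."""
    pid_order = {p: i for i, p in enumerate(design.participant_ids)}
    level_of = {p.id: LEVELS.index(p.career_level) for p in design.participants}
    case_of = {c.id: c for c in design.cases}
    triples = design.eligible_triples()
    p_idx = np.array([pid_order[p] for p, _, _ in triples])
    l_idx = np.array([level_of[p] for p, _, _ in triples])
    q_idx = np.array([q - 1 for _, _, q in triples])
    s_idx = np.array([SPECIMENS.index(case_of[c].specimen) for _, c, _ in triples])
    u_idx = np.array([SUBSPECIALTIES.index(case_of[c].subspecialty) for _, c, _ in triples])
    return triples, p_idx, l_idx, q_idx, s_idx, u_idx


def _draw_effects(params: GenerativeParams, design: StudyDesign, rng: np.random.Generator):
    n_p = len(design.participants)
    sizes = {"beta": len(LEVELS), "gamma": len(CATEGORIES),
             "delta": len(SPECIMENS), "epsilon": len(SUBSPECIALTIES)}
    if params.alpha is not None:
        alpha = np.asarray(params.alpha, dtype=float)
        if alpha.size != n_p:
            raise ValidationError(f"alpha must have length {n_p}")
    else:
        alpha = rng.normal(params.alpha_bar, params.sigma_alpha, size=n_p)
    out = {"alpha": alpha}
    for name, size in sizes.items():
        fixed = getattr(params, name)
        sd = getattr(params, f"sigma_{name}")
        if fixed is not None:
            vec = np.asarray(fixed, dtype=float)
            if vec.size != size:
                raise ValidationError(f"{name} must have length {size}")
        else:
            vec = rng.normal(0.0, sd, size=size)
        out[name] = vec
    return out


def _simulate_flags(
    design: StudyDesign,
    params: GenerativeParams,
    rng: np.random.Generator,
    missing_rate: float,
):
    """Array-level simulation core: (triples, error flags, missing flags)."""
    triples, p_idx, l_idx, q_idx, s_idx, u_idx = _design_indices(design)
    eff = _draw_effects(params, design, rng)
    eta = (
        eff["alpha"][p_idx]
        + eff["beta"][l_idx]
        + eff["gamma"][q_idx]
        + eff["delta"][s_idx]
        + eff["epsilon"][u_idx]
    )
    is_err = rng.random(len(triples)) < expit(eta)
    is_missing = rng.random(len(triples)) < missing_rate
    return triples, is_err, is_missing


def simulate_responses(
    design: StudyDesign,
    params: GenerativeParams,
    seed: int,
    missing_rate: float = DEFAULT_MISSING_RATE,
) -> list[ResponseItem]:
    """Draw one synthetic study from the additive logit-effects model.

    For every eligible (rater, case, question) item the error indicator is
    Bernoulli(inverse-logit(alpha_rater + beta_level + gamma_category +
    delta_specimen + epsilon_subspecialty)); cluster effects are drawn once
    per study.  Missingness is applied independently at ``missing_rate``.
    """
    params.validate()
    if not 0.0 <= missing_rate <= 1.0:
        raise ValidationError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    triples, is_err, is_missing = _simulate_flags(design, params, rng, missing_rate)
    items = []
    for (pid, cid, cat), err, miss in zip(triples, is_err, is_missing):
        outcome = "missing" if miss else ("error" if err else "correct")
        items.append(ResponseItem(pid, cid, cat, outcome))
    return items


# ---------------------------------------------------------------------------
# Reconstruction from marginal tables


def _margin_targets(
    reference: dict[str, GroupErrorTable],
    design: StudyDesign,
    which: str,
) -> list[np.ndarray]:
    """Targets per dimension (pathologist, category, specimen, subspecialty).

    ``which`` is 'n_tasks' or 'n_errors'.
    """
    col = 0 if which == "n_tasks" else 1
    from .data_model import CATEGORY_LABELS

    pid_order = list(design.participant_ids)
    t_p = np.array([reference["pathologist"].rows[p][col] for p in pid_order])
    t_q = np.array(
        [reference["category"].rows[CATEGORY_LABELS[q]][col] for q in CATEGORIES]
    )
    t_s = np.array([reference["specimen"].rows[s][col] for s in SPECIMENS])
    t_u = np.array([reference["subspecialty"].rows[u][col] for u in SUBSPECIALTIES])
    return [t_p, t_q, t_s, t_u]


def _check_reference_consistency(
    reference: dict[str, GroupErrorTable], design: StudyDesign
) -> None:
    needed = {"pathologist", "level", "category", "specimen", "subspecialty"}
    if missing := needed - set(reference):
        raise ValidationError(f"reference marginals missing groupings {sorted(missing)}")
    totals = {g: reference[g].totals for g in needed}
    if len(set(totals.values())) != 1:
        raise ValidationError(f"inconsistent marginals: grouping totals disagree: {totals}")
    # level table must agree with the design's level assignment
    level_of = {p.id: p.career_level for p in design.participants}
    for level, (n_ref, e_ref) in reference["level"].rows.items():
        n = sum(
            reference["pathologist"].rows[p][0]
            for p in design.participant_ids
            if level_of[p] == level
        )
        e = sum(
            reference["pathologist"].rows[p][1]
            for p in design.participant_ids
            if level_of[p] == level
        )
        if (n, e) != (n_ref, e_ref):
            raise ValidationError(
                f"design's career-level assignment cannot carry the level marginals "
                f"({level}: design implies {(n, e)}, reference says {(n_ref, e_ref)})"
            )


def _select_with_margins(
    labels: list[np.ndarray],
    targets: list[np.ndarray],
    rng: np.random.Generator,
    eligible: np.ndarray,
    max_iter: int,
) -> np.ndarray:
    """Select a subset of items hitting exact margins in every dimension.

    Greedy seeded pass, then targeted local search (toggle/swap moves that
    never increase the total L1 margin violation, with occasional sideways
    moves).  Raises if the violation is not driven to zero within
    ``max_iter`` moves.
    """
    n = labels[0].size
    n_dims = len(labels)
    counts = [np.zeros_like(t) for t in targets]
    selected = np.zeros(n, dtype=bool)

    def delta(i: int, turn_on: bool) -> int:
        d = 0
        for dim in range(n_dims):
            lab = labels[dim][i]
            c, t = counts[dim][lab], targets[dim][lab]
            d += (1 if c >= t else -1) if turn_on else (-1 if c > t else 1)
        return d

    def apply(i: int, turn_on: bool) -> None:
        step = 1 if turn_on else -1
        for dim in range(n_dims):
            counts[dim][labels[dim][i]] += step
        selected[i] = turn_on

    order = rng.permutation(np.flatnonzero(eligible))
    for i in order:
        if delta(int(i), True) == -n_dims:
            apply(int(i), True)

    violation = int(sum(np.abs(c - t).sum() for c, t in zip(counts, targets)))
    elig_idx = np.flatnonzero(eligible)

    def targeted(select_state: bool, want_deficit: bool) -> int | None:
        """A random candidate in a deficit (to add) or surplus (to remove) label."""
        if want_deficit:
            lists = [np.flatnonzero(targets[d] - counts[d] > 0) for d in range(n_dims)]
        else:
            lists = [np.flatnonzero(counts[d] - targets[d] > 0) for d in range(n_dims)]
        dims = [d for d in range(n_dims) if lists[d].size]
        if dims:
            d = int(rng.choice(dims))
            lab = int(rng.choice(lists[d]))
            cand = elig_idx[(labels[d][elig_idx] == lab) & (selected[elig_idx] == select_state)]
        else:
            cand = elig_idx[selected[elig_idx] == select_state]
        return int(rng.choice(cand)) if cand.size else None

    for _ in range(max_iter):
        if violation == 0:
            return selected
        move = rng.random()
        if move < 0.4:  # add into a deficit label
            i = targeted(select_state=False, want_deficit=True)
            if i is not None:
                dv = delta(i, True)
                if dv < 0 or (dv == 0 and rng.random() < 0.5):
                    apply(i, True)
                    violation += dv
        elif move < 0.6:  # remove from a surplus label
            i = targeted(select_state=True, want_deficit=False)
            if i is not None:
                dv = delta(i, False)
                if dv < 0 or (dv == 0 and rng.random() < 0.5):
                    apply(i, False)
                    violation += dv
        else:  # paired swap: remove from surplus, add into deficit
            j = targeted(select_state=True, want_deficit=False)
            if j is None:
                continue
            dv_off = delta(j, False)
            apply(j, False)
            i = targeted(select_state=False, want_deficit=True)
            if i is None:
                apply(j, True)
                continue
            dv_on = delta(i, True)
            dv = dv_off + dv_on
            if dv < 0 or (dv == 0 and rng.random() < 0.5):
                apply(i, True)
                violation += dv
            else:
                apply(j, True)
    raise ValidationError(
        "marginal-matching search did not converge within the iteration cap; "
        "try a different seed"
    )


def reconstruct_from_marginals(
    reference: dict[str, GroupErrorTable],
    design: StudyDesign | None = None,
    seed: int = 0,
    max_iter: int = 200_000,
) -> list[ResponseItem]:
    """Build an item-level dataset whose five marginal tables equal ``reference``.

    Two seeded selection problems are solved over the design's eligible
    (rater, case, question) triples: first the missing items (so answered
    counts match per rater, category, specimen and subspecialty), then the
    error flags among answered items.  Fails loudly when the reference is
    internally inconsistent, the design cannot carry the counts, or the
    search hits its iteration cap.
    """
    design = design or table1_design()
    _check_reference_consistency(reference, design)
    rng = np.random.default_rng(seed)
    triples, p_idx, l_idx, q_idx, s_idx, u_idx = _design_indices(design)
    labels = [p_idx, q_idx, s_idx, u_idx]

    answered_targets = _margin_targets(reference, design, "n_tasks")
    error_targets = _margin_targets(reference, design, "n_errors")

    # eligibility capacity per dimension must cover the answered counts
    sizes = [len(design.participants), len(CATEGORIES), len(SPECIMENS), len(SUBSPECIALTIES)]
    for dim, (lab, tgt, size) in enumerate(zip(labels, answered_targets, sizes)):
        cap = np.bincount(lab, minlength=size)
        if np.any(tgt > cap):
            raise ValidationError(
                "design eligibility cannot carry the answered counts "
                f"(dimension {dim}: capacity {cap.tolist()}, needed {tgt.tolist()})"
            )

    # Selecting the small complement (the missing items) is an equivalent but
    # much easier search than selecting the answered items directly.
    capacity = [
        np.bincount(lab, minlength=size) for lab, size in zip(labels, sizes)
    ]
    missing_targets = [cap - tgt for cap, tgt in zip(capacity, answered_targets)]
    all_items = np.ones(len(triples), dtype=bool)
    missing = _select_with_margins(labels, missing_targets, rng, all_items, max_iter)
    answered = ~missing
    errors = _select_with_margins(labels, error_targets, rng, answered, max_iter)

    items = []
    for k, (pid, cid, cat) in enumerate(triples):
        outcome = "error" if errors[k] else ("correct" if answered[k] else "missing")
        items.append(ResponseItem(pid, cid, cat, outcome))
    return items


_FIXTURE_SEED = 170425  # fixed so the packaged fixture is reproducible
_fixture_cache: dict[int, list[ResponseItem]] = {}


def table1_items(seed: int = _FIXTURE_SEED) -> list[ResponseItem]:
    """The canonical reconstructed item-level dataset (memoised per seed)."""
    if seed not in _fixture_cache:
        from .data_model import load_table1

        _fixture_cache[seed] = reconstruct_from_marginals(
            load_table1(), table1_design(), seed=seed
        )
    return list(_fixture_cache[seed])
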