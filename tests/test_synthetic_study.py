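"""Design generation, generative simulation, marginal reconstruction."""

import numpy as np
import pytest
from scipy.special import expit

from dpconcord.data_model import GroupErrorTable, ValidationError, validate_against_marginals
from dpconcord.descriptives import all_error_tables
from dpconcord.synthetic_study import (
    DesignConfig,
    GenerativeParams,
    generate_design,
    reconstruct_from_marginals,
    simulate_responses,
    table1_design,
)


def test_default_design_matches_study_layout():
    design = generate_design()
    assert len(design.participants) == 17
    assert len(design.cases) == 25
    assert design.n_questions_per_participant == 85
    assert design.n_items == 1445
    by_level = {lvl: sum(1 for p in design.participants if p.career_level == lvl)
                for lvl in ("resident", "junior", "expert", "senior")}
    assert by_level == {"resident": 4, "junior": 6, "expert": 5, "senior": 2}
    by_subsp = {s: sum(1 for c in design.cases if c.subspecialty == s)
                for s in ("breast", "urology", "gastrointestinal")}
    assert by_subsp == {"breast": 10, "urology": 5, "gastrointestinal": 10}
    assert sum(1 for c in design.cases if c.specimen == "biopsy") == 14
    assert sum(1 for c in design.cases if c.lesion_class == "malignant") == 10
    grades = sorted(c.grade for c in design.cases if c.lesion_class == "malignant")
    assert grades == [2] * 5 + [3] * 5


def test_custom_eligibility_changes_question_count():
    cfg = DesignConfig(eligibility_counts={1: 25, 2: 17, 3: 25, 4: 10, 5: 10})
    design = generate_design(cfg)
    assert design.n_questions_per_participant == 87


def test_infeasible_eligibility_is_rejected():
    cfg = DesignConfig(eligibility_counts={1: 25, 2: 16, 3: 25, 4: 10, 5: 11})
    with pytest.raises(ValidationError, match="malignant"):
        generate_design(cfg)


def test_design_generation_is_deterministic():
    a = generate_design(DesignConfig(seed=5))
    b = generate_design(DesignConfig(seed=5))
    assert a == b


# --- generative simulation -------------------------------------------------


def _flat_params(alpha_bar):
    return GenerativeParams(
        alpha_bar=alpha_bar, sigma_alpha=0.0, sigma_beta=0.0,
        sigma_gamma=0.0, sigma_delta=0.0, sigma_epsilon=0.0,
    )


@pytest.mark.parametrize("alpha_bar", [0.0, -2.35])
def test_flat_simulation_recovers_inverse_logit_rate(alpha_bar):
    design = generate_design()
    items = simulate_responses(design, _flat_params(alpha_bar), seed=4, missing_rate=0.0)
    rate = sum(it.outcome == "error" for it in items) / len(items)
    p = expit(alpha_bar)
    tol = 3 * np.sqrt(p * (1 - p) / len(items))
    assert abs(rate - p) < tol


def test_missing_rate_one_blanks_everything():
    design = generate_design()
    items = simulate_responses(design, _flat_params(0.0), seed=0, missing_rate=1.0)
    assert all(it.outcome == "missing" for it in items)


def test_simulation_is_deterministic_given_seed():
    design = generate_design()
    params = GenerativeParams(alpha_bar=-2.0)
    assert simulate_responses(design, params, seed=9) == simulate_responses(design, params, seed=9)


def test_group_rates_converge_to_model_implied_rates():
    """Law of large numbers: empirical per-group rates approach the average
    inverse-logit over that group's items, at 50x replication of the cases."""
    k = 50
    cfg = DesignConfig(
        n_per_subspecialty={"breast": 10 * k, "urology": 5 * k, "gastrointestinal": 10 * k},
        n_per_specimen={"biopsy": 14 * k, "surgery": 11 * k},
        n_per_lesion={"nontumoral": 8 * k, "benign": 7 * k, "malignant": 10 * k},
        grade_split=(5 * k, 5 * k),
        eligibility_counts={1: 25 * k, 2: 16 * k, 3: 25 * k, 4: 10 * k, 5: 9 * k},
        seed=1,
    )
    design = generate_design(cfg)
    params = GenerativeParams(
        alpha_bar=-2.0,
        alpha=tuple([-2.0] * 17),
        beta=(0.8, 0.0, -0.2, 0.3),
        gamma=(0.4, -0.6, 0.1, -1.0, 0.9),
        delta=(0.5, -0.3),
        epsilon=(0.3, -0.5, 0.0),
    )
    items = simulate_responses(design, params, seed=77, missing_rate=0.0)
    tables = all_error_tables(items, design)

    from dpconcord.synthetic_study import _design_indices

    triples, p_idx, l_idx, q_idx, s_idx, u_idx = _design_indices(design)
    eta = (
        np.array(params.alpha)[p_idx]
        + np.array(params.beta)[l_idx]
        + np.array(params.gamma)[q_idx]
        + np.array(params.delta)[s_idx]
        + np.array(params.epsilon)[u_idx]
    )
    p_item = expit(eta)
    from dpconcord.data_model import LEVELS, SPECIMENS

    for grouping, idx, order in (("level", l_idx, LEVELS), ("specimen", s_idx, SPECIMENS)):
        tab = tables[grouping]
        for label, (n, e) in tab.rows.items():
            implied = p_item[idx == order.index(label)].mean()
            tol = 4 * np.sqrt(implied * (1 - implied) / n)
            assert abs(e / n - implied) < tol, (grouping, label)


# --- reconstruction --------------------------------------------------------


def test_reconstruction_reproduces_reference_exactly(table1, canonical_design):
    items = reconstruct_from_marginals(table1, canonical_design, seed=3)
    report = validate_against_marginals(items, canonical_design, table1)
    assert report.ok
    tables = all_error_tables(items, canonical_design)
    assert tables["total"].rows["total"] == (1345, 117)


def test_reconstruction_is_seeded_and_nonunique(table1, canonical_design):
    a = reconstruct_from_marginals(table1, canonical_design, seed=1)
    a2 = reconstruct_from_marginals(table1, canonical_design, seed=1)
    b = reconstruct_from_marginals(table1, canonical_design, seed=2)
    assert a == a2
    assert a != b  # the assignment is non-unique; different seeds differ
    for items in (a, b):
        assert validate_against_marginals(items, canonical_design, table1).ok


def test_inconsistent_marginals_are_rejected(table1, canonical_design):
    broken = dict(table1)
    rows = dict(broken["specimen"].rows)
    n, e = rows["biopsy"]
    rows["biopsy"] = (n, e + 1)  # grouping totals now disagree (118 vs 117)
    broken["specimen"] = GroupErrorTable(grouping="specimen", rows=rows)
    with pytest.raises(ValidationError, match="inconsistent marginals"):
        reconstruct_from_marginals(broken, canonical_design, seed=0)


def test_incompatible_level_assignment_is_rejected(table1):
    from dpconcord.data_model import Participant, StudyDesign

    design = table1_design()
    # swap the levels of two raters whose counts differ -> level marginals break
    parts = list(design.participants)
    parts[0] = Participant(parts[0].id, "senior")
    parts[2] = Participant(parts[2].id, "junior")
    bad = StudyDesign(tuple(parts), design.cases)
    with pytest.raises(ValidationError, match="level"):
        reconstruct_from_marginals(table1, bad, seed=0)
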