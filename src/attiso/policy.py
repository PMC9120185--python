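"""Simulated trust-raising interventions and their effect on isolation.

Both policies give 5% of the population a one-point trust increment on one
of the three vaccine items; people already at the all-strong-trust profile
(5,5,5) are never targeted.  They differ in whom they reach:

* policy1 targets people who are almost, but not completely, convinced —
  mixed profiles holding at least one strong-trust (5) and at least one
  weak-trust (4) attitude.  Converting their weak attitudes to strong ones
  depletes the people who link the strong- and weak-trust attitudes, so
  attitude-isolation *increases*.
* policy2 targets people holding only weak-trust attitudes (4,4,4);
  promoting one attitude to 5 creates new mixed profiles, couples the
  strong-trust attitudes back to the rest, and isolation *decreases*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .attitude_network import attitude_isolation
from .survey_core import SurveyDataset

__all__ = ["PolicySpec", "PolicyOutcome", "eligible", "apply_policy"]

POLICIES = ("policy1", "policy2")


@dataclass
class PolicySpec:
    policy_id: str = "policy2"
    coverage: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.policy_id not in POLICIES:
            raise ValueError(f"unknown policy {self.policy_id!r}")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")


@dataclass
class PolicyOutcome:
    isolation_before: float
    isolation_after: float
    n_targeted: int

    @property
    def percent_change(self) -> float:
        """100 * (after - before) / |before|; sign is the direction of change."""
        return 100.0 * (self.isolation_after - self.isolation_before) / abs(
            self.isolation_before
        )


def eligible(policy_id: str, codes) -> bool:
    """Whether a respondent's three vaccine codes qualify for targeting.

    Respondents with any missing code, or the full strong-trust profile
    (5,5,5), are never eligible.
    """
    codes = np.asarray(codes, dtype=float)
    if codes.shape != (3,):
        raise ValueError("expected exactly 3 vaccine codes")
    if np.isnan(codes).any():
        return False
    if (codes == 5).all():
        return False
    if policy_id == "policy1":
        return bool((codes == 5).any() and (codes == 4).any())
    if policy_id == "policy2":
        return bool((codes == 4).all())
    raise ValueError(f"unknown policy {policy_id!r}")


def apply_policy(
    data: SurveyDataset, spec: PolicySpec, predicate=None
) -> tuple[SurveyDataset, PolicyOutcome]:
    """Run one simulated intervention and re-measure attitude-isolation.

    floor(coverage * N) eligible respondents are drawn uniformly without
    replacement (all of them if fewer are eligible); each receives +1 on
    one uniformly chosen vaccine attitude that is not already at the
    maximum.  Non-vaccine items are untouched.  Returns the modified
    dataset and the before/after isolation.  ``predicate(codes) -> bool``
    overrides the built-in eligibility rule (the (5,5,5) exemption is
    still enforced).
    """
    vax_ids = [it.item_id for it in data.vaccine_items]
    if len(vax_ids) != 3:
        raise ValueError(f"expected exactly 3 vaccine items, found {len(vax_ids)}")
    codes = data.codes(vax_ids).to_numpy(dtype=float)
    if predicate is None:
        ok = np.array([eligible(spec.policy_id, row) for row in codes])
    else:
        ok = np.array(
            [
                not np.isnan(row).any() and not (row == 5).all() and bool(predicate(row))
                for row in codes
            ]
        )
    n_target = min(int(spec.coverage * len(data)), int(ok.sum()))
    before = attitude_isolation(data).isolation

    rng = np.random.default_rng(spec.seed)
    new_codes = codes.copy()
    if n_target == 0:
        warnings.warn(f"{spec.policy_id}: no respondents targeted")
    else:
        chosen = rng.choice(np.flatnonzero(ok), size=n_target, replace=False)
        for i in chosen:
            slots = np.flatnonzero(new_codes[i] < 5)
            new_codes[i, rng.choice(slots)] += 1

    table = data.table.copy()
    table[vax_ids] = new_codes
    modified = SurveyDataset(table, data.items)
    after = attitude_isolation(modified).isolation
    return modified, PolicyOutcome(before, after, n_target)
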