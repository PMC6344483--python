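"""Shared fixtures: small seeded synthetic sessions and hand-built trials."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from goodspace import behavior, synth
from goodspace.task_core import OfferType, Session, Trial, TrialEvents

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


DEFAULT_EVENTS = TrialEvents(offer_on=1.5, offer_off=2.5, target_on=3.5,
                             go=4.3, saccade=4.5, juice=5.25)


def make_trial(index: int, qA=1, qB=2, costA="low", offerA_side="L",
               angleA=157.5, chosen="B", prev_juice="none", prev_cost="none",
               events=DEFAULT_EVENTS) -> Trial:
    costB = "high" if costA == "low" else "low"
    angleB = {22.5: 202.5, 157.5: 337.5, 202.5: 22.5, 337.5: 157.5}[angleA]
    return Trial(index=index, offer=OfferType(qA, qB, costA, costB),
                 offerA_side=offerA_side, angleA=angleA, angleB=angleB,
                 chosen_juice=chosen, events=events,
                 prev_chosen_juice=prev_juice, prev_chosen_cost=prev_cost)


def make_session(trial_params: list[dict], session_id="toy") -> Session:
    """Session from a list of make_trial keyword dicts; history filled in."""
    trials = []
    prev_j, prev_c = "none", "none"
    for i, params in enumerate(trial_params, start=1):
        t = make_trial(i, prev_juice=prev_j, prev_cost=prev_c, **params)
        trials.append(t)
        prev_j, prev_c = t.chosen_juice, t.chosen_cost
    return Session(session_id=session_id, trials=trials)


@pytest.fixture(scope="session")
def small_session():
    """400-trial counterbalanced session, default generating indices."""
    return synth.generate_session(synth.GeneratorConfig(seed=11, trials_per_condition=10))


@pytest.fixture(scope="session")
def small_config():
    return synth.GeneratorConfig(seed=11, trials_per_condition=10)


@pytest.fixture(scope="session")
def small_fit(small_session):
    return behavior.fit_choice_model(small_session)
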