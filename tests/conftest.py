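import numpy as np
import pytest

from commgem.assembly import build_community_model, set_medium
from commgem.fixtures import (
    make_biogas_toy,
    make_chain_community,
    make_cycle_community,
)
from commgem.member_prep import prepare_member


def build_fixture(fixture):
    """Prepare members and assemble the community for a FixtureSpec."""
    members = [prepare_member(m, m.id) for m in fixture.members]
    cm = build_community_model(members)
    set_medium(cm, fixture.medium)
    return members, cm


def original_uptake_medium(member) -> dict[str, float]:
    """Medium reproducing a member's original exchange uptake bounds."""
    medium = {}
    for twin, transport_id in member.exchange_transports.items():
        lb = member.model.reaction(transport_id).lower_bound
        if lb < 0:
            medium[twin] = -lb
    return medium


def simplex_grid(n_members: int, step: float = 0.1):
    """All compositions on the n-simplex with the given grid step."""
    k = round(1.0 / step)
    if n_members == 2:
        return [(i / k, (k - i) / k) for i in range(k + 1)]
    if n_members == 3:
        return [
            (i / k, j / k, (k - i - j) / k)
            for i in range(k + 1)
            for j in range(k + 1 - i)
        ]
    raise ValueError(n_members)


@pytest.fixture
def chain2():
    fixture = make_chain_community()
    members, cm = build_fixture(fixture)
    return fixture, members, cm


@pytest.fixture
def cycle2():
    fixture = make_cycle_community()
    members, cm = build_fixture(fixture)
    return fixture, members, cm


@pytest.fixture
def biogas():
    fixture = make_biogas_toy()
    members, cm = build_fixture(fixture)
    return fixture, members, cm


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)
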