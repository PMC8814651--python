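import numpy as np
import pytest

from foodlit.instrument import bundled_iflt
from foodlit.scoring import Response


@pytest.fixture(scope="session")
def inst():
    return bundled_iflt()


def max_ios_answers(inst):
    return {
        it.item_id: max(range(len(it.options)), key=lambda i: it.options[i].ios)
        for it in inst.items
    }


def min_ios_answers(inst):
    return {
        it.item_id: min(range(len(it.options)), key=lambda i: it.options[i].ios)
        for it in inst.items
    }


def zero_ips_answers(inst):
    """One answer per item signalling no need on every linked goal."""
    answers = {}
    for it in inst.items:
        for i, opt in enumerate(it.options):
            if all(opt.ips_for(g) == 0 for g in it.goal_ids):
                answers[it.item_id] = i
                break
    return answers


def random_response(inst, rng, respondent_id="rnd"):
    return Response(
        respondent_id,
        {it.item_id: int(rng.integers(0, len(it.options))) for it in inst.items},
    )


@pytest.fixture
def perfect_response(inst):
    return Response("perfect", max_ios_answers(inst))


@pytest.fixture
def worst_response(inst):
    return Response("worst", min_ios_answers(inst))


@pytest.fixture
def zero_ips_response(inst):
    return Response("no-need", zero_ips_answers(inst))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
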