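"""Shared fixtures: inventories, toy rule sets, and small simulations."""

from __future__ import annotations

import pytest
from hypothesis import settings

from graphovar.inventory import (
    GPCRule,
    Grapheme,
    GraphemeInventory,
    default_inventory,
)
from graphovar.phonology import default_phoneme_inventory
from graphovar.simulate import SimulationParams, simulate_responses

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phinv():
    return default_phoneme_inventory()


@pytest.fixture(scope="session")
def inv():
    return default_inventory()


#: toy inventory over the letters {B, R, E, C}: ten context-free graphemes,
#: used to compare enumerate_parses against an exhaustive segmentation oracle
TOY_PATTERNS = ("B", "R", "E", "C", "BR", "RE", "EC", "CC", "BRE", "REC")


@pytest.fixture(scope="session")
def toy_inv(phinv):
    phoneme_for = {
        "B": "b", "R": "r", "E": "ɛ", "C": "k", "BR": "b",
        "RE": "ɛ", "EC": "ɛ", "CC": "k", "BRE": "b", "REC": "r",
    }
    rules = []
    for i, pat in enumerate(TOY_PATTERNS):
        ph = phinv[phoneme_for[pat]]
        klass = "vowel" if ph.is_vowel else "consonant"
        rules.append(GPCRule(Grapheme(pat, "any", "", klass), ph, precedence=i))
    return GraphemeInventory(
        rules, name="toy", phoneme_inventory=phinv, require_full_alphabet=False
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally complete simulated dataset (8 x 60)."""
    params = SimulationParams(n_subjects=8, n_nonwords=60, seed=11)
    records, truth = simulate_responses(params)
    return params, records, truth


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation (45 subjects x 412 nonwords)."""
    params = SimulationParams(seed=7)
    records, truth = simulate_responses(params)
    return params, records, truth
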