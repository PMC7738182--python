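"""Shared fixtures: small hand-checkable landscapes and oracle helpers."""

from __future__ import annotations

import math
from itertools import permutations

import pytest
from hypothesis import settings

from fitscape.landscape import FitnessLandscape, FitnessMeasurement, Substitution

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_landscape(effects: dict[str, float], folds: dict[str, float], name: str = "toy") -> FitnessLandscape:
    """Build a landscape from explicit genotype->fold values."""
    subs = sorted(Substitution.parse(s) for s in effects)
    measurements = {g: FitnessMeasurement(mean=f) for g, f in folds.items()}
    return FitnessLandscape(subs, measurements, name=name)


def multiplicative_landscape(single_folds: dict[str, float], name: str = "mult") -> FitnessLandscape:
    """Complete landscape where every genotype's fold is the product of singles."""
    labels = sorted(single_folds, key=lambda s: Substitution.parse(s).position)
    subs = [Substitution.parse(s) for s in labels]
    folds: dict[str, float] = {}
    n = len(labels)
    for mask in range(2**n):
        present = [subs[i] for i in range(n) if mask >> i & 1]
        fold = math.prod(single_folds[labels[i]] for i in range(n) if mask >> i & 1)
        key = "+".join(str(s) for s in sorted(present)) or "WT"
        folds[key] = fold
    return make_landscape({s: 0.0 for s in labels}, folds, name=name)


def brute_force_accessible(landscape: FitnessLandscape, threshold: float = 0.16) -> int:
    """Independent oracle: re-walk every permutation using genotype strings only."""
    subs = [str(s) for s in landscape.substitutions]
    count = 0
    for perm in permutations(subs):
        acquired: list[str] = []
        f = landscape.mean("WT")
        ok = True
        for s in perm:
            acquired.append(s)
            key = "+".join(
                sorted(acquired, key=lambda t: Substitution.parse(t).position)
            )
            f_next = landscape.mean(key)
            if not f_next > f * (1 + threshold):
                ok = False
                break
            f = f_next
        count += ok
    return count


@pytest.fixture
def toy3() -> FitnessLandscape:
    """Three-substitution landscape with a mix of improving and blocked steps."""
    folds = {
        "WT": 1.0,
        "A1V": 1.5,
        "C2W": 0.8,
        "D3Y": 1.1,
        "A1V+C2W": 2.5,
        "A1V+D3Y": 1.9,
        "C2W+D3Y": 0.9,
        "A1V+C2W+D3Y": 4.0,
    }
    return make_landscape({"A1V": 0, "C2W": 0, "D3Y": 0}, folds)
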