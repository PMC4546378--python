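"""Shared fixtures: small synthetic trials kept cheap for unit tests."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import settings

from cqtkit.design import TrialDesign, build_design
from cqtkit.ecg import build_observations
from cqtkit.simulate import QtModelParams, simulate_ecg, simulate_pk, simulate_trial

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: reduced ECG schedule for fast model fits (pre-dose, around-Cmax, meals, late)
SMALL_TIMES = (0.0, 1.0, 2.0, 6.0, 8.0, 24.0)


def small_design(n_subjects: int = 8, times=SMALL_TIMES) -> TrialDesign:
    return dataclasses.replace(build_design(n_subjects), nominal_times_h=tuple(times))


def small_trial(n_subjects=8, seed=11, qt_params=None, times=SMALL_TIMES):
    """A reduced-schedule trial: (design, pk, ecg)."""
    design = small_design(n_subjects, times)
    pk = simulate_pk(design, seed=seed)
    ecg = simulate_ecg(design, pk, qt_params, seed=seed + 1)
    return design, pk, ecg


@pytest.fixture(scope="session")
def null_trial():
    """Drug-free default-noise trial on the reduced schedule."""
    return small_trial(n_subjects=8, seed=11)


@pytest.fixture(scope="session")
def null_observations(null_trial):
    design, pk, ecg = null_trial
    obs, corrections = build_observations(ecg, pk, design.subjects_frame())
    return obs, corrections


@pytest.fixture(scope="session")
def drug_trial():
    """Reduced-schedule trial with a linear QTc-shortening drug effect."""
    params = QtModelParams(drug_slope=-0.0008)
    return small_trial(n_subjects=12, seed=29, qt_params=params)


@pytest.fixture(scope="session")
def drug_observations(drug_trial):
    design, pk, ecg = drug_trial
    obs, _ = build_observations(ecg, pk, design.subjects_frame())
    return obs


@pytest.fixture(scope="session")
def full_trial():
    """Full 19-time-point default trial (session-scoped; used sparingly)."""
    design, pk, ecg = simulate_trial(n_subjects=16, seed=5)
    obs, corrections = build_observations(ecg, pk, design.subjects_frame())
    return design, pk, ecg, obs, corrections
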