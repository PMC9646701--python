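import numpy as np
import pytest

from eyeblink.cr_metrics import score_cohort
from eyeblink.preprocess import NormalizedTrial
from eyeblink.simulate import SimParams, TrialRecord, simulate_cohort


def make_trial(samples, trial_type="CS_ONLY", fps=300.0, cs_onset_index=None,
               us_onset_index=None, isi_ms=250.0, mouse="m1", day=1, trial=1,
               genotype="WT"):
    """TrialRecord around a raw sample vector (defaults: CS at mid-trace)."""
    samples = np.asarray(samples, dtype=float)
    if cs_onset_index is None:
        cs_onset_index = len(samples) // 2
    if us_onset_index is None and trial_type != "CS_ONLY":
        us_onset_index = cs_onset_index + int(round(fps * isi_ms / 1000.0))
    return TrialRecord(
        mouse_id=mouse, genotype=genotype, day=day, phase="ISI250", block=1,
        trial=trial, trial_type=trial_type, isi_ms=isi_ms, fps=fps,
        cs_onset_index=cs_onset_index, us_onset_index=us_onset_index,
        samples=samples)


def make_normalized(nec, fps=300.0, cs_onset_index=None, valid=True,
                    trial_type="CS_ONLY", isi_ms=250.0, mouse="m1", day=1,
                    trial=1, genotype="WT"):
    nec = np.asarray(nec, dtype=float)
    if cs_onset_index is None:
        cs_onset_index = 0
    return NormalizedTrial(
        mouse_id=mouse, genotype=genotype, day=day, phase="ISI250", block=1,
        trial=trial, trial_type=trial_type, isi_ms=isi_ms, fps=fps,
        cs_onset_index=cs_onset_index, us_onset_index=None, nec=nec,
        valid=valid, norm_factor=1.0, baseline_offset=0.0)


@pytest.fixture(scope="session")
def noise_free_params():
    return SimParams(n_per_genotype=2, days_phase1=3, days_phase2=3,
                     n_blocks=6, noise_sd=0.0, artifact_prob=0.0, seed=11)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_params):
    """Simulated noise-free cohort plus its scored outputs (computed once)."""
    trials, truth = simulate_cohort(noise_free_params)
    cr, summaries, qc = score_cohort(trials)
    return dict(trials=trials, truth=truth, cr=cr, summaries=summaries, qc=qc)


@pytest.fixture(scope="session")
def noisy_cohort():
    params = SimParams(n_per_genotype=3, days_phase1=2, days_phase2=2,
                       n_blocks=5, noise_sd=0.05, artifact_prob=0.05, seed=21)
    trials, truth = simulate_cohort(params)
    cr, summaries, qc = score_cohort(trials)
    return dict(params=params, trials=trials, truth=truth, cr=cr,
                summaries=summaries, qc=qc)
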