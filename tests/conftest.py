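"""Shared fixtures: device specs and small synthetic datasets.

All data is generated at test time from fixed seeds; nothing is read from
disk.  The session-scoped separable benchmark is shared by the slower
classifier tests so the dataset is synthesized once.
"""

import numpy as np
import pytest

import ptfm
from ptfm import train_eval as te


@pytest.fixture(scope="session")
def device():
    """The PVDF device: f0 = 8.5 kHz, Q = 27.6, 28 um film, 5 mm diameter."""
    return ptfm.default_resonator()


@pytest.fixture(scope="session")
def quartz():
    """A 5 MHz quartz-substrate resonator for the Sauerbrey path."""
    return ptfm.ResonatorSpec(f0_hz=5e6, area_cm2=1.0, rho_q=2.648,
                              mu_q=2.947e11)


@pytest.fixture(scope="session")
def probe_excitation(device):
    """Square-wave harmonic probe at f0/3: the third harmonic sits on the
    resonance, so harmonic amplitude ratios encode the mass load and survive
    per-segment peak normalization."""
    return ptfm.ExcitationSpec(waveform="square", frequency_hz=device.f0_hz / 3)


def make_benchmark(device, probe_excitation, n_per_class, seed=1,
                   separation_scale=40.0, snr_db=30.0):
    ds = ptfm.build_dataset(device, probe_excitation, list(range(10)),
                            n_per_class, ptfm.NoiseSpec(snr_db=snr_db),
                            seed=seed, separation_scale=separation_scale)
    return te.split_dataset(ds, te.SplitSpec(seed=seed))


@pytest.fixture(scope="session")
def tiny_benchmark(device, probe_excitation):
    """10 classes x 20 segments: enough for pipeline and metric tests."""
    return make_benchmark(device, probe_excitation, n_per_class=20)


@pytest.fixture(scope="session")
def separable_benchmark(device, probe_excitation):
    """The well-separated synthetic benchmark at 250 segments/class used by
    the architecture accuracy checks."""
    return make_benchmark(device, probe_excitation, n_per_class=250)


@pytest.fixture(scope="session")
def two_tone_toy():
    """Two trivially separable classes: pure 2 kHz vs 6 kHz tones at 30 dB
    SNR (100 train / 50 val per the convergence check)."""
    rng_fs, dur = 48000.0, 0.1
    dev = ptfm.default_resonator()
    segs, labels = [], []
    for i, f in enumerate((2000.0, 6000.0)):
        exc = ptfm.ExcitationSpec(waveform="sine", frequency_hz=f)
        for rep in range(150):
            segs.append(ptfm.synth_segment(
                dev, exc, 0.0, ptfm.NoiseSpec(snr_db=30.0), fs=rng_fs,
                duration=dur, seed=10_000 * i + rep))
            labels.append(float(i))
    ds = ptfm.LabeledDataset(segments=segs, labels=np.array(labels),
                             classes=[0.0, 1.0], seed=0)
    return te.split_dataset(ds, te.SplitSpec(fractions=(1 / 3, 1 / 6, 0.5),
                                             seed=0))
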