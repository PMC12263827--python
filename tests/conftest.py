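"""Shared fixtures: grids, rendered transits, and small survey simulations."""

from __future__ import annotations

import pytest
from dataclasses import replace

from entolidar.spectral import make_grid, modulation_spectrum
from entolidar.synthetic import (
    build_class_library,
    build_schedule,
    generate_noise_fragments,
    reference_wing_templates,
    render_transit,
    sample_events,
)
from entolidar.events import filter_events


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def wing_templates():
    return reference_wing_templates()


@pytest.fixture(scope="session")
def fixture_transits(wing_templates):
    """Noiseless 500 ms transits of the three reference wing types."""
    return {
        t.class_id: render_transit(t, 500.0, t.wbf_mean, phase=0.7, noise_sd=0.0, seed=1)
        for t in wing_templates
    }


@pytest.fixture(scope="session")
def dense_schedule():
    """1-day schedule with a 50% duty cycle — fast event simulation."""
    return build_schedule(days=1.0, dwell_s=30.0, repositioning_pause_s=30.0)


def simulate_spectra(library, schedule, grid, seed, base_rate, noise_sd=0.02):
    """Render a survey and return (accepted events, their spectra)."""
    events = filter_events(sample_events(library, schedule, base_rate, seed, noise_sd=noise_sd))
    spectra = [modulation_spectrum(ev, grid) for ev in events]
    return events, spectra


def separable_library(n_classes, separation, seed=1):
    """Well-separated class library used by recovery-style tests."""
    return build_class_library(n_classes, seed=seed, separation=separation)


def noise_spectra_set(n, seed, grid):
    frags = generate_noise_fragments(n, seed=seed)
    return [modulation_spectrum(f, grid) for f in frags]


def layered_library(n_per_layer, separation, seed):
    """Classes resident in exactly one layer, interleaved over the
    frequency ladder so layer identity is not a frequency band."""
    K = sum(n_per_layer)
    lib = build_class_library(K, seed=seed, separation=separation)
    onehot = (
        [(1.0, 0.0, 0.0)] * n_per_layer[0]
        + [(0.0, 1.0, 0.0)] * n_per_layer[1]
        + [(0.0, 0.0, 1.0)] * n_per_layer[2]
    )
    order = sorted(range(K), key=lambda i: i % 3)
    lw = [None] * K
    for rank, i in enumerate(order):
        lw[i] = onehot[rank]
    return [replace(t, layer_weights=lw[i]) for i, t in enumerate(lib)]
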