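"""Shared fixtures: synthetic scenes are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import calyxmorph as cm
from calyxmorph import stereology as ste


@pytest.fixture(scope="session")
def morpho_bundle():
    """12-cell tonotopic-line scene with calyces, boutons and pigments."""
    cfg = cm.SimulationConfig.morphometry(seed=11)
    volume, table, manifest = cm.generate_dataset(cfg)
    return cfg, volume, table, manifest


@pytest.fixture(scope="session")
def morpho_graph(morpho_bundle):
    _, volume, table, _ = morpho_bundle
    return cm.build_contact_graph(volume, table)


@pytest.fixture(scope="session")
def degen_bundle():
    """8-cell scene with fragmented calyces and roughened somas."""
    cfg = cm.SimulationConfig.degeneration_preset(seed=21)
    volume, table, manifest = cm.generate_dataset(cfg)
    return cfg, volume, table, manifest


@pytest.fixture(scope="session")
def stereo_bundle():
    """320-cell gradient field for density estimation."""
    cfg = cm.SimulationConfig.stereology(seed=5)
    volume, table, manifest = cm.generate_dataset(cfg)
    frame = cm.TonotopicFrame.from_volume(volume)
    pn_ids = [p.pn_id for p in manifest.pns]
    footprints = ste.CellFootprints(volume, pn_ids)
    return cfg, volume, manifest, frame, footprints


def make_ball_volume(radius_um=5.0, pitch_nm=(250.0, 250.0, 250.0), label=7):
    """A single digital ball in a small labeled volume (test helper)."""
    from calyxmorph._morph import digital_ball_mask

    pitch_um = np.asarray(pitch_nm) / 1000.0
    ball = digital_ball_mask(radius_um, pitch_um)
    labels = np.zeros(np.array(ball.shape) + 4, dtype=np.int32)
    labels[2:-2, 2:-2, 2:-2][ball] = label
    return cm.AnnotatedVolume(labels, tuple(pitch_nm))
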