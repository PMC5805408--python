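"""Shared fixtures: synthetic movies run once per session and reused.

The expensive fixtures (full 40-frame movies through segmentation and
tracking) are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from follipulse import segtrack
from follipulse.synthgen import TissueSpec, gen_pulsing_tissue


@dataclass
class Pipeline:
    """A generated movie taken through segmentation and tracking."""

    spec: TissueSpec
    stack: object
    truth: object
    masks: np.ndarray
    tracked: np.ndarray
    table: object
    tracks: list

    @property
    def interior_true_labels(self) -> np.ndarray:
        lab = self.truth.label_stack[0]
        border = np.unique(np.r_[lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        all_ids = np.unique(lab)
        return np.setdiff1d(all_ids[all_ids > 0], border)


def run_pipeline(spec: TissueSpec) -> Pipeline:
    stack, truth = gen_pulsing_tissue(spec)
    masks = segtrack.segment_stack(stack)
    tracked = segtrack.track_cells(masks)
    table = segtrack.measure_tracks(tracked, stack)
    tracks = segtrack.table_to_tracks(table, full_length_only=True)
    return Pipeline(spec, stack, truth, masks, tracked, table, tracks)


@pytest.fixture(scope="session")
def pipeline_lag2() -> Pipeline:
    """Default-noise 40-frame movie, myosin leading by 2 frames.

    Rectangular field along AP so the amplitude gradient spans a wide
    range of distances from the pole.
    """
    return run_pipeline(
        TissueSpec(
            n_cells=100, field_size=(160, 400), pixel_size=0.25,
            n_frames=40, myosin_lag_frames=2, seed=7,
        )
    )


@pytest.fixture(scope="session")
def pipeline_aniso2() -> Pipeline:
    """Movie with imposed ML/AP pulse anisotropy ratio 2."""
    return run_pipeline(
        TissueSpec(
            n_cells=60, field_size=200, n_frames=40, anisotropy_ratio=2.0, seed=8
        )
    )


@pytest.fixture(scope="session")
def polarity_frames():
    """One enriched (x2 on 70-90 deg bonds) and one unpolarized frame."""
    out = {}
    for name, enr in (("enriched", 2.0), ("null", 1.0)):
        spec = TissueSpec(
            n_cells=200, field_size=384, n_frames=2, bond_enrichment=enr, seed=5
        )
        stack, truth = gen_pulsing_tissue(spec)
        labels = segtrack.segment_frame(stack.data[0, 0], stack.pixel_size_um)
        bonds = segtrack.extract_bonds(
            labels, {"membrane": stack.data[0, 0]}, stack.pixel_size_um
        )
        out[name] = {
            "spec": spec, "stack": stack, "truth": truth,
            "labels": labels, "bonds": bonds,
        }
    return out


@pytest.fixture(scope="session")
def noisefree_tissue():
    """Small noise-free movie for exact-recovery segmentation checks."""
    spec = TissueSpec(
        n_cells=50, field_size=256, n_frames=2, seed=3, noise_model=None
    )
    stack, truth = gen_pulsing_tissue(spec)
    return spec, stack, truth
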