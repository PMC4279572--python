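"""Shared fixtures.

Expensive full-bundle simulations (flat/arc reduction set, complete
pipeline run) are session-scoped so the suite renders them once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from fibercube import simulate as sim
from fibercube.config import PipelineConfig
from fibercube.geometry import BundleLayout
from fibercube.models import Frame
from fibercube.pipeline import PipelineResult, run_pipeline
from fibercube.reduce import combine_bias, extract, find_traces


@pytest.fixture(scope="session")
def layout() -> BundleLayout:
    return BundleLayout()


@pytest.fixture(scope="session")
def detector() -> sim.DetectorConfig:
    return sim.DetectorConfig()


@pytest.fixture(scope="session")
def library() -> sim.SpectralLibrary:
    return sim.default_library()


def small_config(**overrides) -> PipelineConfig:
    """A fast 6x6-bundle configuration for integration-style tests."""
    kwargs = dict(
        layout=BundleLayout(n_rows=6, n_cols=6),
        # full column count: coarser dispersion would undersample the
        # 12 cm^-1 peaks (profile sigma < 1 px looks like a cosmic)
        detector=sim.DetectorConfig(n_rows_px=320, n_cols_px=600),
        axis=(200.0, 2000.0, 4.0),
        phantom="half_field",
        n_cosmics=5,
        seed=11,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@dataclass
class CalibrationSet:
    """Full-bundle flat/arc/bias simulation plus found traces."""

    layout: BundleLayout
    detector: sim.DetectorConfig
    traces_true: sim.TraceModel
    dispersion_true: sim.DispersionModel
    throughput_true: np.ndarray
    arc_lines: np.ndarray
    master: Frame
    flat: Frame
    arc: Frame
    traces_found: sim.TraceModel


@pytest.fixture(scope="session")
def calib(layout, detector) -> CalibrationSet:
    rng = np.random.default_rng(42)
    traces = sim.default_traces(layout, detector)
    dispersion = sim.default_dispersion(layout, detector)
    throughput = sim.throughput_factors(traces.n_traces, rng)
    flat = sim.make_flat(traces, detector, throughput, rng=rng)
    arc_lines = sim.default_arc_lines()
    arc = sim.make_arc(arc_lines, traces, dispersion, detector, rng=rng)
    master = combine_bias(sim.make_bias(detector, 3, rng=rng))
    flat_sub = Frame(flat.data - master.data, "flat", flat.exptime)
    found = find_traces(flat_sub, expected_n=layout.n_fibers,
                        n_slots=layout.n_fibers)
    return CalibrationSet(layout=layout, detector=detector, traces_true=traces,
                          dispersion_true=dispersion,
                          throughput_true=throughput, arc_lines=arc_lines,
                          master=master, flat=flat, arc=arc,
                          traces_found=found)


@pytest.fixture(scope="session")
def flat_rss(calib):
    return extract(calib.flat, calib.traces_found, calib.master)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory) -> PipelineResult:
    """Seed-7 full pipeline run on the bead phantom.

    One fiber away from all beads is dead so mask propagation and the
    white-spaxel rendering convention can be checked on the same run.
    """
    cfg = PipelineConfig(seed=7,
                         layout=BundleLayout(dead_fibers={(13, 2)}))
    outdir = tmp_path_factory.mktemp("run7")
    return run_pipeline(cfg, outdir)
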