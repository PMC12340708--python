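"""Shared fixtures: small simulated cohorts and helpers reused across tests."""

from collections import defaultdict
from pathlib import Path

import numpy as np
import pytest

from rohpipe import simgenome as sg
from rohpipe import rohcall as rc

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_vcf_path() -> Path:
    return DATA_DIR / "toy_filters.vcf"


@pytest.fixture(scope="session")
def small_layout() -> sg.GenomeLayout:
    return sg.GenomeLayout.uniform(n_chrom=10, chrom_length_bp=50_000_000)


@pytest.fixture(scope="session")
def planted_cohort(small_layout):
    """Capture-style cohort: 20 inbred (ages 5/15/25, 25% of genome) + 6 outbred."""
    cfg = sg.SimConfig(
        seed=42,
        n_individuals=20,
        n_outbred=6,
        n_populations=1,
        depth_mean=10,
        snp_spacing_bp=50_000,
        error_rate=0.01,
        roh_age_spec=[(5, 0.25 / 3), (15, 0.25 / 3), (25, 0.25 / 3)],
    )
    return sg.simulate_cohort(cfg, small_layout)


@pytest.fixture(scope="session")
def planted_cohort_calls(planted_cohort):
    segments, info = rc.call_roh_cohort(planted_cohort.table, planted_cohort.populations)
    return segments, info


def segments_by_individual(segments):
    out = defaultdict(list)
    for s in segments:
        out[(s.individual, s.chrom)].append((s.start, s.end))
    return out


def truth_detected(truth_seg, called_index, min_reciprocal=0.5) -> bool:
    """A truth tract is detected if some call reciprocally overlaps >= 50%."""
    tlen = truth_seg.end - truth_seg.start + 1
    for a, b in called_index[(truth_seg.individual, truth_seg.chrom)]:
        ov = min(b, truth_seg.end) - max(a, truth_seg.start) + 1
        if ov > 0 and ov >= min_reciprocal * tlen and ov >= min_reciprocal * (b - a + 1):
            return True
    return False


def sensitivity(truth, segments, min_len) -> tuple[float, int]:
    idx = segments_by_individual(segments)
    tracts = [t for t in truth if t.length >= min_len]
    if not tracts:
        return float("nan"), 0
    hits = sum(truth_detected(t, idx) for t in tracts)
    return hits / len(tracts), len(tracts)
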