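"""Shared fixtures: small synthetic configurations and random-record factories."""

from __future__ import annotations

import numpy as np
import pytest

from svscen.io import SVRecord
from svscen.merge import MergeParams
from svscen.pipeline import run_synthetic_pipeline
from svscen.simulate import SimConfig

SMALL_COHORTS = {"A": {"SR": 4, "LR": 2}, "B": {"SR": 3, "LR": 2}}


def small_config(**overrides) -> SimConfig:
    """A fast 2 x 200 kb configuration used by most unit tests."""
    defaults = dict(
        contig_length=200_000,
        n_fixed_sv_per_species=8,
        n_polymorphic_sv=4,
        n_artefact_sv=2,
        samples_per_species={k: dict(v) for k, v in SMALL_COHORTS.items()},
        fn_rate=0.0,
        fp_rate_per_mbp=0.0,
        breakpoint_jitter_sd=0.0,
        seed=1,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def noise_free_run():
    """One noise-free end-to-end run shared by read-only tests."""
    return run_synthetic_pipeline(small_config(), MergeParams())


@pytest.fixture
def params() -> MergeParams:
    return MergeParams()


def random_records(rng: np.random.Generator, n: int, n_contigs: int = 2,
                   span_max: int = 100_000) -> list[SVRecord]:
    """Random SV records for clustering oracle tests (TRA mates canonical)."""
    types = ["DEL", "DUP", "INS", "INV", "TRA"]
    out = []
    for _ in range(n):
        svtype = types[int(rng.integers(len(types)))]
        contig = f"ctg{int(rng.integers(n_contigs)) + 1}"
        start = int(rng.integers(1, span_max))
        caller = f"c{int(rng.integers(3)) + 1}"
        sample = f"s{int(rng.integers(4)) + 1}"
        support = int(rng.integers(0, 30))
        if svtype == "INS":
            rec = SVRecord(contig, start, start, "INS", int(rng.integers(50, 500)),
                           support=support, caller=caller, sample=sample)
        elif svtype == "TRA":
            mate = (f"ctg{int(rng.integers(n_contigs)) + 1}", int(rng.integers(1, span_max)))
            c, p, m = (contig, start, mate) if (contig, start) <= mate else (
                mate[0], mate[1], (contig, start))
            rec = SVRecord(c, p, p, "TRA", 0, mate=m,
                           support=support, caller=caller, sample=sample)
        else:
            size = int(rng.integers(50, 3000))
            rec = SVRecord(contig, start, start + size, svtype, size,
                           support=support, caller=caller, sample=sample)
        out.append(rec)
    return out
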