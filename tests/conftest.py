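import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pirnakit import mapping, synthetic

settings.register_profile(
    "det", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def single_copy_locus() -> synthetic.LocusSpec:
    """One-copy transgene locus: every read is a unique mapper."""
    return synthetic.LocusSpec(
        n_copies=1, unit_length=1500, chrom_length=8000, insert_position=3000
    )


@pytest.fixture(scope="session")
def single_copy_refs(single_copy_locus):
    refs, ann = synthetic.build_reference(single_copy_locus, seed=11)
    return refs, ann


@pytest.fixture(scope="session")
def tandem_locus() -> synthetic.LocusSpec:
    """Seven-copy tandem locus: repeat reads are inherent multi-mappers."""
    return synthetic.LocusSpec(
        n_copies=7, unit_length=300, chrom_length=10_000, insert_position=4000
    )


@pytest.fixture(scope="session")
def tandem_refs(tandem_locus):
    return synthetic.build_reference(tandem_locus, seed=11)


@pytest.fixture(scope="session")
def pingpong_hits(single_copy_locus, single_copy_refs):
    """A ping-pong library trimmed, mapped to the transgene unit, 23-29 nt."""
    refs, _ = single_copy_refs
    spec = synthetic.LibrarySpec(
        n_pirna=4000, n_sirna=400, n_mirna=500, pingpong_fraction=0.5, seed=7
    )
    raw = synthetic.simulate_small_rna_library(refs, single_copy_locus, spec)
    trimmed = mapping.trim_library(raw)
    unit = synthetic.unit_reference(refs, single_copy_locus)
    res = mapping.map_reads(trimmed, unit, max_mismatches=0)
    hits = mapping.filter_by_length(list(res.hits), 23, 29)
    reads = {r.id: r.seq for r in trimmed}
    return hits, reads


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def brute_force_placements(read, references, max_mm):
    """Exhaustive per-position Hamming scan: the mapper's independent oracle."""
    out = set()
    for name, ref in references.items():
        ref_arr = encode(ref)
        for strand, query in (("+", read.seq), ("-", mapping.revcomp(read.seq))):
            L = len(query)
            if L > len(ref):
                continue
            wins = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
            dists = (wins != encode(query)).sum(axis=1)
            for start in np.nonzero(dists <= max_mm)[0]:
                out.add((read.id, name, int(start), int(start) + L, strand, int(dists[start])))
    return out
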