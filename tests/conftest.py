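"""Shared fixtures: a study-scale simulated capture/shotgun experiment.

The ``study`` fixture is the standard scenario used by several tests:
a 16.5 kb ancestral bait source, a descendant whose divergence spans
0-27% (mean 12%), and 20,000-fragment capture and shotgun libraries at
the generator's default damage, retention and duplication settings,
taken through MAPQ filtering, deduplication and the window analysis.
It is computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from anccap import baitdesign, dedup, seqio, simgen, windows


def make_read(
    start: int,
    end: int,
    bases: str | None = None,
    strand: str = "+",
    mapq: int = 60,
    name: str = "r",
    ref_id: str = "ref",
) -> seqio.AlignedRead:
    if bases is None:
        bases = "A" * (end - start)
    return seqio.AlignedRead(
        name=name, ref_id=ref_id, start=start, end=end, strand=strand, mapq=mapq, bases=bases
    )


@pytest.fixture(scope="session")
def study():
    anc = simgen.generate_ancestral(16500, 0.40, seed=11)
    track = simgen.default_divergence_track(16500)
    desc, truth = simgen.evolve_descendant(anc, track, seed=12)
    baits = baitdesign.design_baits(anc)
    frag = simgen.FragmentModel(n_fragments=20000)
    damage = simgen.DamageModel()
    capture_model = simgen.CaptureModel()  # p_max=0.95, id_50=0.80, slope=40
    cap = simgen.simulate_library(
        desc, frag, damage, "capture", baits=baits, capture=capture_model,
        dup_rate=0.15, seed=13, sample_id="cap",
    )
    sho = simgen.simulate_library(
        desc, frag, damage, "shotgun", dup_rate=0.15, seed=14, sample_id="sho"
    )
    cap_unique, _ = dedup.mark_duplicates_start_end(seqio.filter_mapq(cap.reads))
    sho_unique, _ = dedup.mark_duplicates_start_end(seqio.filter_mapq(sho.reads))
    params = windows.WindowParams()
    wins = windows.window_identity(anc.bases, desc.bases, params)
    windows.window_depth(cap_unique, wins, len(anc), which="capture")
    windows.window_depth(sho_unique, wins, len(anc), which="shotgun")
    return {
        "ancestor": anc,
        "descendant": desc,
        "truth": truth,
        "track": track,
        "baits": baits,
        "capture_model": capture_model,
        "cap_lib": cap,
        "sho_lib": sho,
        "cap_unique": cap_unique,
        "sho_unique": sho_unique,
        "windows": wins,
        "window_params": params,
    }


def random_reads(rng: np.random.Generator, n: int, ref_length: int, ref_id: str = "ref"):
    """Small random read sets for oracle comparisons."""
    reads = []
    for i in range(n):
        ln = int(rng.integers(10, min(61, ref_length)))
        s = int(rng.integers(0, ref_length - ln + 1))
        bases = "".join(rng.choice(list("ACGTN"), size=ln, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(make_read(s, s + ln, bases, strand, name=f"r{i}", ref_id=ref_id))
    return reads
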