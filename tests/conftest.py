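import numpy as np
import pytest

from mitokit.simulate import (
    GenePlan,
    MtptSpec,
    RepeatSpec,
    SimConfig,
    TrnaSpec,
    generate_mt_genome,
)


@pytest.fixture(scope="session")
def small_genome():
    """One scaled-down genome + cp partner + truth, shared across tests."""
    return generate_mt_genome(SimConfig.small(seed=5))


def tiny_mtpt_config(seed: int, divergences=None) -> SimConfig:
    """Minimal configuration for plastid-scan tests: few genes, no repeats,
    a hard mix of insert sizes and divergences including the worst case
    (near-minimum length at the identity floor)."""
    divergences = divergences or [0.19, 0.2, 0.15, 0.05, 0.1, 0.0]
    sizes = [36, 30, 60, 75, 400, 1200]
    klasses = ["other", "other", "tRNA", "tRNA", "photosynthesis", "other"]
    plan = [
        MtptSpec(s, klass=k, divergence=d, strand="+" if i % 2 else "-")
        for i, (s, k, d) in enumerate(zip(sizes, klasses, divergences))
    ]
    genes = [
        GenePlan("cox1", exon_lengths=(900,)),
        GenePlan("atp9", exon_lengths=(312,)),
        GenePlan("rrn18", category="rRNA", exon_lengths=(1200,)),
    ]
    trnas = [TrnaSpec("trnE(TTC)", "native"), TrnaSpec("trnW(CCA)", "cp_like")]
    return SimConfig(
        seed=seed,
        length=20_000,
        cp_length=30_000,
        genes=genes,
        trnas=trnas,
        repeat_plan=[],
        mtpt_plan=plan,
    )


def tiny_repeat_config(seed: int, divergence: float = 0.0) -> SimConfig:
    """Minimal configuration for repeat-recall suites."""
    rng = np.random.default_rng(seed)
    plan = [
        RepeatSpec(int(rng.integers(1000, 3000)), divergence=divergence),
        RepeatSpec(int(rng.integers(200, 600)),
                   orientations=("+", "-"), divergence=divergence),
        RepeatSpec(int(rng.integers(60, 120)), copies=3,
                   orientations=("+", "+", "-"), divergence=divergence),
        RepeatSpec(int(rng.integers(20, 40))),
    ]
    genes = [GenePlan("cob", exon_lengths=(600,))]
    return SimConfig(
        seed=seed,
        length=16_000,
        cp_length=30_000,
        genes=genes,
        trnas=[],
        repeat_plan=plan,
        mtpt_plan=[],
    )


def interval_overlap(a, b) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def family_recovers(found_families, truth_family, frac=0.9) -> bool:
    """True if one found family covers every planted copy of the truth."""
    return any(
        all(
            any(
                interval_overlap(c.interval, iv) >= frac * (iv.end - iv.start + 1)
                for c in f.copies
            )
            for iv, _ in truth_family["copies"]
        )
        for f in found_families
    )
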