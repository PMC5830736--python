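import numpy as np
import pytest

from songdyad import simulate
from songdyad.types import DyadScenario, PhraseAnnotation, SingerTrack


@pytest.fixture
def scenario() -> DyadScenario:
    """Default study geometry: onset at 45 min, 45-min periods, 15-min windows."""
    return DyadScenario("F", "S", onset_s=2700.0, seed=11, mc_reps=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def simple_annotations() -> list[PhraseAnnotation]:
    """One singer, phrases A, A, B back to back from t = 0."""
    return [
        PhraseAnnotation("F", 0.0, 10.0, "A"),
        PhraseAnnotation("F", 10.0, 20.0, "A"),
        PhraseAnnotation("F", 20.0, 30.0, "B"),
    ]


@pytest.fixture
def straight_track() -> SingerTrack:
    """Constant-velocity eastward track sampled every 150 s over 45 min."""
    t = np.arange(0.0, 2700.0 + 1, 150.0)
    return SingerTrack("F", t, 1.0 * t, np.zeros_like(t))


def random_annotations(
    rng: np.random.Generator, n: int, singer_id: str = "F", types: str = "ABCDE"
) -> list[PhraseAnnotation]:
    """Non-overlapping random phrases on a millisecond grid (round-trip safe)."""
    out = []
    t_ms = 0
    for _ in range(n):
        t_ms += int(rng.integers(0, 5000))
        dur_ms = int(rng.integers(3000, 30000))
        out.append(
            PhraseAnnotation(
                singer_id,
                t_ms / 1000.0,
                (t_ms + dur_ms) / 1000.0,
                str(rng.choice(list(types))),
            )
        )
        t_ms += dur_ms
    return out


@pytest.fixture
def dyad_factory():
    """Synthesise a dyad's annotations/tracks for a given seed and coupling."""

    def make(seed: int, coupling: float = 0.0, mc_reps: int = 200):
        sc = DyadScenario("F", "S", onset_s=2700.0, seed=seed, mc_reps=mc_reps)
        params = simulate.DyadGenParams(coupling_m=coupling, seed=seed)
        annotations, tracks = simulate.simulate_dyad(params, sc)
        return sc, annotations, tracks

    return make
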