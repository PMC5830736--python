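# songdyad

Song-sequence and movement analyses for interacting humpback whale singers.

Male humpback whales (*Megaptera novaeangliae*) sing long, cyclical songs
built from a shared repertoire of phrase types, repeating each type several
times before switching (*eventual variety*). When a second male starts
singing nearby, does the first change how he sings and moves? `songdyad`
implements the metrics and resampling tests used to answer that question
from passive-acoustic annotations and localization tracks:

- **Switching rate** — `SR = Tn / (Pn − 1)`, transitions between phrase
  types over one less than the phrase count, per 15-min window, averaged
  over the BEFORE (focal singing alone) and DURING (both singing) periods.
- **Relative song evenness** — a normalized Shannon index over the singer's
  current repertoire of `k` phrase types,
  `J′ = −Σᵢ pᵢ log pᵢ / log k ∈ [0, 1]`,
  1 when every type is sung equally often, 0 when one type monopolises.
- **Phrase-type overlap ("song matching")** — both singers' phrase types are
  sampled every 8 s across the DURING period; the observed proportion of
  co-sampled instants with matching types is tested against a Monte Carlo
  null built by re-starting the second singer's whole sequence (order and
  durations preserved) at 1000 random times in the BEFORE period.
- **Movement** — separation distances at the window endpoints, change in
  distance (negative = approach), and the meander ratio (path length /
  straight-line chord, over 5-min bins; 1 = straight travel, ≫ 1 = milling),
  tested against a null from all pairwise superpositions of solo singers
  recorded at non-overlapping times.
- **Synthetic data** — seeded generators for eventual-variety songs (with a
  tunable switching probability and inter-singer matching coupling) and
  correlated-random-walk tracks, so the full pipeline is testable without
  field recordings.

The intended users are bioacousticians and behavioural ecologists analysing
countersinging or display interactions from annotated selection tables
(Raven-style TSV) and localization tracks (CSV).

## Worked example

Simulate one dyad whose second singer matches the focal's current phrase
type with probability 0.8, then run the song-pattern metrics and the
time-shift overlap test:

```python
from songdyad.types import DyadScenario
from songdyad import simulate, matching, song_metrics

scenario = DyadScenario("focal01", "second01", onset_s=2700.0, seed=42)
params = simulate.DyadGenParams(coupling_m=0.8, seed=42)
annotations, tracks = simulate.simulate_dyad(params, scenario)

windows = song_metrics.segment_windows(scenario, scenario.before_start_s)
rep = song_metrics.observed_repertoire(annotations, "focal01")
before = song_metrics.period_metrics(
    annotations, "focal01",
    [w for w in windows if w.period_label == "BEFORE"], rep)
during = song_metrics.period_metrics(
    annotations, "focal01",
    [w for w in windows if w.period_label == "DURING"], rep)
print(f"focal SR  BEFORE {before.mean_switching_rate:.3f}  DURING {during.mean_switching_rate:.3f}")
print(f"focal J'  BEFORE {before.mean_evenness:.3f}  DURING {during.mean_evenness:.3f}")

res = matching.mc_overlap_test(annotations, annotations, scenario)
print(f"observed overlap {res.observed_overlap:.3f}  "
      f"expected {res.mean_expected_overlap:.3f}  p_right {res.p_right:.3f}")
```

which prints

```
focal SR  BEFORE 0.113  DURING 0.127
focal J'  BEFORE 0.767  DURING 0.689
observed overlap 0.873  expected 0.154  p_right 0.014
```

The focal singer switches phrase types about 11–13% of the time; the dyad's
observed 8-s overlap (0.873) far exceeds the mean overlap expected if the
two songs were independent (0.154), and only about 1.4% of the 1000
time-shifted null replicates reach it — strong evidence of matching, which
is exactly what the generator's coupling injected.

There is also a CLI for file-based workflows:

```sh
songdyad simulate --out data/ --seed 5 --n-dyads 3 --n-solo 18
songdyad report --config data/study.json --out report/
```

`report/` then holds per-dyad song-pattern and matching tables, spatial and
meander tables with their tests, an exclusion list, and a JSON manifest of
every parameter and seed.

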