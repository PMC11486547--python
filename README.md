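# lockbox

Decompositional analysis of sequential puzzle-box ("lockbox") solving from
coded contact-event logs, plus a constraint-driven agent simulator for
validating the whole pipeline.

## The problem

In mechanical problem-solving experiments (e.g. Goffin's cockatoos working a
baited lockbox), a subject faces a strictly sequential apparatus: a wheel
must be rotated and pulled off its axle, then a bar shifted aside, then the
door opened.  Observation videos are coded into timestamped *contact events*
(wheel / bar / door / other surface) across repeated 15-minute sessions.
The raw learning curve — time-to-solution `T` per *solution episode* — mixes
several adaptive processes.  This package factors it exactly:

```
T = (n_a / n_c) · n_c · (T / n_a) = M · E · Δ
```

* `M = n_a / n_c` — **mistargeting of actions**: total contacts per
  correctly targeted contact, where "correct" means on the one component
  that can currently advance the task. `M = 1` is perfectly task-directed
  behaviour; `p = 1/M` is the probability of touching a functionally
  relevant part.
* `E = n_c` — **effort**: correctly targeted contacts needed to open all
  locks, a proxy for sensorimotor skill.
* `Δ = T / n_a` — **inter-contact interval**: seconds per contact,
  operationalising engagement.

The decomposition is a mathematical identity, so the three factors jointly
reconstruct performance; each can adapt on its own schedule.  Slow strategy
learning is summarised by an OLS fit of `ln M` against solution index
(excluding the first solution by default).

Episodes may span sessions (a subject can carry a half-opened box into the
next day); segmentation tracks the task state machine across sessions,
accumulates in-session time only, and flags an unfinished trailing episode.

## Who it is for

Behavioural scientists with ethogram-style event logs from sequential
puzzle tasks (BORIS exports map directly onto the CSV dialect described in
`lockbox/io_ethogram.py`), and modellers who want a generative baseline:
the simulator produces logs whose statistical structure mirrors the
behavioural constraints seen in such studies (fast adaptation after the
first success, slow log-linear decline of mistargeting, occasional
regression to naive behaviour, inter-individual variation).

## Worked example

Five contacts, solved at 50 s — states run wheel, wheel, wheel, bar, door:

```python
import lockbox as lb

session = lb.SessionRecord(
    "bird1", 1, 50.0, "wheel_locked",
    [
        lb.ContactEvent(10.0, "wheel"),
        lb.ContactEvent(20.0, "bar"),                  # stray: bar touched in wheel state
        lb.ContactEvent(30.0, "wheel", opens_lock=True),
        lb.ContactEvent(40.0, "bar", opens_lock=True),
        lb.ContactEvent(50.0, "door", opens_lock=True),
    ],
)
(episode,) = lb.segment_episodes([session])
rec = lb.compute_decomposition(episode)
print(rec.n_a, rec.n_c, rec.M, rec.E, rec.delta_s, rec.T_s)
```

prints

```
5 4 1.25 4 10.0 50.0
```

Five contacts, four of them correct, so `M = 5/4 = 1.25`; effort `E = 4`;
one contact every `Δ = 10` s — and `1.25 · 4 · 10.0 = 50.0 = T` exactly.

The same pipeline from the shell:

```
lockbox simulate --preset birdlike --seed 7 --outdir sim/
lockbox analyze  --input sim/events.csv --outdir out/
```

writes `out/metrics.csv` (one row per solution with `T_s, n_a, n_c, n_w,
n_b, n_d, M, E, delta_s`) and `out/report.json` with the per-subject
`ln M` trend fit.  `lockbox recover` compares pipeline estimates on
simulated data against the generating parameters.

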