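# affectdyn

Dyadic affect dynamics for psychotherapy process research: turn
per-second SPAFF affect codes for a therapist–client pair into weighted
score series, compare sessions with small-sample Kolmogorov–Smirnov
tests, fit a coupled dynamical-systems model of the dyad, and draw its
phase portrait with attractors and the session's projected trajectory.

The package targets researchers who code recorded therapy (or other
dyadic) interactions with the Specific Affect Coding System — 20
mutually exclusive codes per second per actor (Neutral, seven
positive-leaning codes such as Affection, Humor, High/Low Validation,
Interest, and twelve negative codes such as Contempt, Criticism,
Tension, Sadness) — and want a tested, reproducible path from those
streams to quantitative relationship dynamics. Its packaged fixtures
carry the published per-session aggregates of a six-session course of
mindfulness-based relapse-prevention therapy, so every reported summary
statistic can be recomputed without the (undeposited) raw recordings.

## The model

Each second's code is mapped to a signed weight (e.g. Affection +4,
Low Validation +2, Neutral +0.1, Tension −1, Contempt −4; fully
configurable) and summed over consecutive 6-s windows, giving one score
per window per actor (150 points per 15 min). The dyad's windowed
scores $(T_t, C_t)$ then evolve by a coupled discrete-time map

$$T_{t+1} = r_T T_t + a_T + I_C(C_t) + R_C(C_t)$$
$$C_{t+1} = r_C C_t + a_C + I_T(T_t) + R_T(T_t)$$

where $r$ is the actor's emotional **inertia**, $a$ the **initial
state** (uninfluenced disposition), $I$ the partner's piecewise-linear
**influence function** — zero in a dead zone between a negative
threshold *nth* and a positive threshold *pth*, linear outside —
and $R$ an optional **repair** term: a constant positive boost of
strength *sr* when the partner's score drops below a threshold *kr*.
Without influence an actor relaxes to the **uninfluenced steady state**
$\mathrm{UnSS} = a/(1-r)$. Parameters are estimated by least squares:
$(a, r)$ from partner-neutral transitions, thresholds by scanning the
observed partner scores, then one joint pass for all linear terms.
Fixed points of the map (attractors, saddles, repellers) are computed
exactly per affine region; the quadrant an attractor occupies —
e.g. therapist-positive/client-negative, the classic "working"
quadrant — summarizes the relationship regime.

Sessions are compared per code by a one-sample KS test of the n
per-session percentages against a reference fitted to the sample
(normal with mean and n−1 SD, or exponential with rate 1/mean), with
an exact small-sample or parametric-bootstrap p-value.

## Worked example

Simulate three coded sessions, summarize, compare codes across
sessions, fit the dyad model for session 1, and render its portrait:

```python
from affectdyn import StreamSpec, generate_stream, summarize
from affectdyn.io import write_session, write_summary

summaries = []
for s in range(1, 4):
    t = generate_stream(StreamSpec("therapist", 1800,
        {"Neutral": 0.88, "Low Validation": 0.06, "Interest": 0.03, "Tension": 0.03},
        persistence=0.7, seed=10 + s))
    c = generate_stream(StreamSpec("client", 1800,
        {"Neutral": 0.75, "Tension": 0.12, "Sadness": 0.08,
         "High Validation": 0.03, "Anger": 0.02},
        persistence=0.7, seed=20 + s))
    if s == 1:
        write_session(t, c, "session1.csv")
    summaries += [summarize(t, f"s{s}"), summarize(c, f"s{s}")]
write_summary(summaries, "summary.csv")
```

```bash
$ affectdyn ks --summary summary.csv --actor client --kind code --reference exponential --out ks.csv
wrote KS table (20 variables) to ks.csv
$ affectdyn fit --session session1.csv --epsilon 0.6 --out params.csv
wrote fitted parameters to params.csv
$ affectdyn portrait --params params.csv --out portrait.png --critical-out critical.csv
wrote portrait with 1 critical point(s) to portrait.png
```

The KS table gives, per code, the sup-distance D of the six-session
percentages from the fitted reference and its p-value (codes never
observed are flagged `degenerate (all zero)`); for this client's Anger
stream it prints `D = 0.415, p = 0.554` — no evidence the sessions
differ. The parameter CSV mirrors the standard layout, `N/A` marking
regimes the data cannot support:

```
actor,a2,r2,UnSS,nth,pth,kr,sr
therapist,1.1259771255663829,0.3842136383295881,1.8285191028135193,-4.9,-1.6,N/A,N/A
client,-0.02113791080521857,0.19196236722858206,-0.026159562312363462,8.2,10.1,N/A,N/A
```

and the portrait's critical-point CSV locates a single attractor at
(T, C) = (1.83, −3.97) in the therapist-positive/client-negative
quadrant: the therapist holds a mildly positive steady state while the
client is pulled negative — the "working" configuration in which the
client struggles and the therapist supports.

`--epsilon` is the neutral band: transitions where the partner's
window score lies within ±ε are treated as uninfluenced when
estimating (a, r). Under the default weights an all-Neutral window
scores 6 × 0.1 = 0.6, hence ε = 0.6 here.

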