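# efos — state-transition analysis of table tennis rallies

`efos` implements the **enhanced first-offensive-shot (EFOS) model**: a
rally in table tennis is described as a walk through an absorbing state
machine

```
SER → (DEF)* → FOS#i → FOS+1 → FOS+2 → FOS+3 → (OFF)* → {P, E}
```

where `SER` is the serve, `DEF` a defensive (backspin) return, `FOS#i`
the **first offensive shot** split by the shot number on which it occurs
(`FOS#2` attacks the serve, `FOS#3` the first defensive return,
`FOS#>=4` any later shot), `FOS+1..FOS+3` the three shots after it, and
`OFF` the subsequent open offensive exchange.  `P` (point) and `E`
(error) are the absorbing outcomes.  States group into three phases:
pre-offensive (`SER`, `DEF`), initial-offensive (the six FOS-window
states) and final-offensive (`OFF`).

The package is for performance analysts and sports scientists working
with notational rally codings.  A rally is recorded with six criteria
(gender, server, rally length, FOS number, FOS player, winner); from
these the full state sequence is derived deterministically.  On top of
that the package provides:

- **Transition estimation** — `P(X→Y)` = transitions from `X` to `Y`
  over shots originating from `X`, per player-side, per match, pooled,
  and unweighted unit averages (`efos.transitions`).
- **Absorbing-chain analytics** — closed-form reach probabilities,
  per-state ending shares and the phase-ending distribution by
  first-step analysis with geometric-series handling of the `DEF`/`OFF`
  self-loops (`efos.chain`).
- **Rate statistics** — direct/overall winning rates, usage rates and
  the two-consecutive-attacks connection rate per FOS category
  (`efos.rates`).
- **Nonparametric group comparisons** — Mann–Whitney U with
  rank-biserial `r = |z|/√N`, Kruskal–Wallis H with
  `ε² = H(n+1)/(n²−1)`, Holm-adjusted pairwise tests, a KS normality
  screen, and Cohen's κ for coder reliability (`efos.stats`).
- **A rally simulator** — position-aware walks through the chain with
  group-level parameter shifts, emergent match results and full
  ground-truth event logs, so every pipeline stage is testable without
  match videos (`efos.simulate`).

A packaged fixture ships the published averaged transition matrix of
105 elite singles matches (9,925 rallies) from the Tokyo 2020 Olympic
tournament, stored exactly as printed (percent, 3 significant figures).

## Worked example

Where do rallies end, given the packaged averaged matrix?

```python
from efos import absorption_profile, load_reference_matrix, renormalize_rows

profile = absorption_profile(renormalize_rows(load_reference_matrix()))
print(profile.phase_share.round(3).to_dict())
print(round(profile.fos_containing, 3))
```

prints

```
{'POP': 0.095, 'IOP': 0.706, 'FOP': 0.199}
0.905
```

i.e. 9.5% of rallies never leave defensive play, 70.6% are decided in
the initial-offensive phase (the FOS and the three shots after it) and
19.9% in the later offensive exchange; 90.5% of rallies contain a first
offensive shot.  `examples/` holds one short script per capability
(absorption profile, simulation + parameter recovery, group
comparison, rates, reliability); each prints its numbers with a line on
how to read them.  A thin CLI mirrors the pipeline stages:

```bash
efos simulate --seed 1 --out records.csv
efos absorb                      # absorption profile of the packaged matrix
efos compare --records records.csv --factor gender --out gender.csv
```

## Layout

```
src/efos/        model, transitions, chain, rates, stats, simulate, io, cli
src/efos/data/   packaged averaged transition matrix (CSV, as printed)
examples/        narrative scripts, one per capability
tests/           pytest suite (unit, property and end-to-end checks)
docs/methods.md  modelling assumptions, conventions and limitations
```
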