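# eagleadapt

Adaptive-management decision analysis for recreational restrictions at
golden eagle (*Aquila chrysaetos*) nesting territories, built as a
belief-state Markov decision process with an informative success signal.

## The problem

A park manages N = 25 eagle nesting territories reachable by hikers.  Each
spring the number of occupied territories S is known, and the manager
closes A ≤ S of them to hikers for the breeding season.  Restriction
protects fledging success if hiker disturbance is real — but how strong the
disturbance effect is, is precisely what is not known.  Three candidate
models (no / moderate / strong disturbance) are carried with belief weights
**B**, and every year the observed fledging successes and next-year
occupancy update those weights by Bayes rule.  Good management must balance
three things at once: breeding success, hiker access, and the value of the
information each action generates.

## The model

Per site and year, with hare abundance index *h*:

* colonization of an empty site: `p_c`;
* fledging success: `p_r = logistic(β_INT + β_HARE·h)` if restricted,
  `p_u = logistic(β_INT + β_DIST + β_HARE·h)` if unrestricted;
* re-occupancy next year: `p_s` after success, `p_n` after failure.

Because sites are exchangeable, the N-site kernel
`P(Y₁, Y₂, S⁺ | S, A)` — counts of unrestricted/restricted successes and
next-year occupancy — is built exactly by multinomial category counting.
The decision problem is solved on the occupancy count × belief simplex:

    V(S, B) = max_{A ≤ S} { E[Y|S,A,B]^α (N−A)^(1−α)
                            + δ Σ_{Y,S⁺} P_B(Y,S⁺|S,A) V(S⁺, B⁺(Y,S⁺)) }

with α = 0.85, δ = 0.98, and `B⁺` the Bayes posterior.  Active strategies
solve this fixed point (and may *probe* — deviate to learn faster);
passive strategies re-solve a frozen-belief MDP at each B.  Signals are
compared in the Blackwell ordering (existence of a garbling matrix, found
by linear programming), and learning speed is measured by Monte-Carlo
expected belief paths.

## A worked example

`examples/06_learning_curves.py` simulates 1000 management histories under
the p_r-known uncertainty case when the strong-disturbance model is true,
updating beliefs with three different signals:

```
expected weight on the true model (strong_disturbance),
1000 paths, initial beliefs uniform, 20 of 25 sites occupied:

  year     full    total     none
     1    0.467    0.467    0.333
     5    0.707    0.708    0.334
    10    0.825    0.804    0.334
    25    0.938    0.905    0.337
    50    0.985    0.954    0.340
   100    0.997    0.981    0.344
```

Reading the columns: using the per-category success counts (`full`) drives
the expected belief in the true model from ⅓ to ≈1 within a few decades;
pooling successes into one total is nearly as fast; updating from occupancy
transitions alone (`none`, the traditional adaptive-management information
set) learns essentially nothing in a century, because re-occupancy barely
differs after successful (0.9573) and failed (0.9427) seasons.

The other examples build the single-site event table and the published
two-site kernel (`01`, `02`), certify that the success outcome
Blackwell-dominates the action as a signal (`03`), reproduce the
certain-model restriction rules across hare levels (`04`), and map probing
and the percent value of the signal on the belief simplex (`05`).  A thin
CLI wraps the same calls: `eagle-adapt solve|simulate|tables --help`.

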