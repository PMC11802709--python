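# flocknet

Association inference and social network comparison for RFID detection
streams from bird feeders.

## The problem

Automated RFID feeders log a timestamped detection every time a
PIT-tagged bird lands on an antenna. Behavioural ecologists turn these
streams into social networks via the *gambit of the group*: individuals
detected in the same grouping event are assumed to be pairwise
associated. But what counts as "the same grouping event" is a
methodological choice, and different choices may produce different
networks from the same data. `flocknet` implements three widely used
association definitions and the machinery to compare them:

1. **Strict time window** — detections at one location are chained
   whenever consecutive reads fall within Δt (default 1 s) of each
   other; everyone in a chain is one group. This is the transitive
   closure of the pairwise within-Δt relation.
2. **Gathering events (GMM)** — detection times are segmented into
   bursts of feeder activity by a one-dimensional Gaussian mixture whose
   number of components is chosen by BIC; everyone detected in a burst
   is one group. The event windows adapt to the data instead of being
   fixed.
3. **Arrival time** — the chain rule is applied to *arrival events*
   (first detection after an absence of at least Δi, default 300 s)
   with Δt = 150 s, so birds are associated by arriving together, and a
   bird sitting on the feeder all morning cannot bridge unrelated
   groups.

Each definition yields a binary group-by-individual (GBI) matrix, which
is scaled into a weighted undirected network by the **simple ratio
index**: for a dyad (a, b),

    SRI(a, b) = x / (x + y_a + y_b)

where `x` counts groups containing both individuals and `y_a`, `y_b`
count groups containing one but not the other. Node metrics are degree
(unique associates), strength (summed edge weights) and weighted
betweenness (geodesic counts on reciprocal-weight costs).

Networks built from the same stream under different definitions are
compared by Jaccard similarity over edges and over closed triangles, a
simple MRQAP regression of one scaled adjacency matrix on the other
(node-label permutation significance) and a Mantel test. Significance
against chance grouping uses the *pre-network permutation* null: each
individual's GBI column is shuffled without replacement, preserving how
often each bird was detected while randomising who with.

Whether individual network position is a stable trait is measured by
**repeatability**: metrics are extracted from weekly sub-networks,
z-scored within week, and decomposed as

    y_iw = mu + alpha_i + eps_iw,    R = var(alpha) / (var(alpha) + var(eps))

with variance components estimated by one-way ANOVA moments (equal to
REML on balanced designs) and a parametric-bootstrap 95% CI. A Δt
sensitivity sweep recomputes R over a grid of time windows.

Because real streams come with unknown social structure, the package
ships a synthetic flock-foraging simulator (`flocknet.synthetic`) with
latent social units, correlated flock arrivals, a repeatable
individual sociability trait and configurable feeder architectures
(open antenna, entry chamber, perch array), so every stage can be
validated against known ground truth.

## Worked example

```python
from flocknet import (WorldConfig, make_world, simulate_detections, detect,
                      AssociationParams, build_sri_network, prune_isolates,
                      network_summary, compare_networks)

cfg = WorldConfig(n_individuals=20, n_units=4, n_weeks=4, seed=1)
world = make_world(cfg)
stream = simulate_detections(world, week=0)
print(f"{len(stream)} detections of {len(stream.individuals)} birds")

gbi_w = detect(stream, "window", AssociationParams(delta_t=1.0))
gbi_a = detect(stream, "arrival", AssociationParams(delta_t=150.0, delta_i=300.0))
net_w = prune_isolates(build_sri_network(gbi_w))
net_a = prune_isolates(build_sri_network(gbi_a))
for name, gbi, net in [("window", gbi_w, net_w), ("arrival", gbi_a, net_a)]:
    s = network_summary(net)
    print(f"{name:8s} {gbi.n_groups:4d} groups -> V={s.V} E={s.E} D={s.D:.2f}")

res = compare_networks(net_w, net_a, n_perm=999, seed=0)
print(f"jaccard_edges={res.jaccard_edges:.2f}  mrqap={res.mrqap_coef:.2f} "
      f"(p={res.mrqap_p:.3f})  mantel_r={res.mantel_r:.2f} (p={res.mantel_p:.3f})")
```

prints

```
36974 detections of 20 birds
window   3011 groups -> V=20 E=158 D=0.83
arrival   175 groups -> V=20 E=184 D=0.97
jaccard_edges=0.85  mrqap=0.95 (p=0.001)  mantel_r=0.95 (p=0.001)
```

One simulated week of a 20-bird population yields ~37k reads. The
strict window cuts them into 3011 small groups, the arrival definition
into 175 larger ones; the resulting networks share 85% of their dyads,
and each strongly predicts the other's edge weights (MRQAP slope 0.95,
significant against 999 node permutations).

The same workflow is available from the shell:

```sh
flocknet simulate --seed 1 --out run/
flocknet detect run/detections_week00.csv --method arrival --delta-t 150 \
    --delta-i 300 --out run/gbi.csv
flocknet build run/gbi.csv --out run/net.csv
flocknet run config.yaml      # full pipeline from a YAML RunConfig
```

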