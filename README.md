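# priornet

Expression-filtered analysis of prior-knowledge networks.

Curated interaction databases describe a theoretical whole-genome cell:
molecules end up connected that are never co-expressed in any real
tissue. Expression profiling, conversely, says which genes are present
in a sample but predicts nothing about how they interact. `priornet`
combines the two without inferring a single new edge: a directed
reference network (signaling reactions, or enzyme adjacency derived
from a reaction table) is restricted to the genes *detected* in a
tag-count expression experiment, and the filtered networks are then
validated and mined — pathway over-representation against an
expression-weighted null, key-node scoring by pairwise
disconnectivity, and bow-tie structure versus differential expression.
It is aimed at systems-biology analysts who have a curated network, a
presence/absence expression readout, and a pathway collection, and who
want statistically careful statements about what the filtered network
contains.

Because the original inputs of this kind (curated signaling and
metabolic databases, SAGE tag libraries, multi-tissue microarray
compendia) are licensed resources, the package ships a first-class
synthetic generator that reproduces their scale and statistical
structure, so the entire pipeline is testable end to end from a single
seed.

## Methods in brief

**Filtering.** For a reference digraph G = (V, E) and detected vertex
set D ⊆ V, the *strict* network is the induced subgraph G[D]; the
*1-extended* network is G[D ∪ N(D)] with N(D) the in- and
out-neighbors of D. Detection is presence-based (≥ 1 tag by default),
and the two conditions' detected sets are combined by union by
default (intersection and symmetric difference are available).

**Enrichment.** Under the refined null, universe gene *i* is drawn
with probability proportional to its overall expression
E_i = Σ_j A_ij across a tissue panel A. For a pathway of size K in a
universe of size N with filtered-set size n and overlap k, the null
overlap distribution is the noncentral (Fisher) hypergeometric law

    f(x) ∝ C(K, x) · C(N−K, n−x) · ω^x ,

with odds ω = mean(E_i : i ∈ pathway) / mean(E_i : i ∉ pathway), and
the one-tailed p-value is P(X ≥ k). For 1-extended networks, where
the extension step correlates genes, strict-size sets are redrawn from
the weighted null, 1-extended, and an empirical p-value
(1 + #{o_t ≥ o_obs}) / (1 + T) is computed from T = 10⁴ samples. The
classical central Fisher test (ω = 1) is kept as a baseline, and
multiplicity is controlled by Storey q-values (positive FDR), which
remain valid for these discrete, conservative p-values.

**Key nodes.** The pairwise disconnectivity index of vertex v is the
fraction of initially connected ordered vertex pairs that lose their
connection when v is removed, Dis(v) = (N₀(v) − N₋ᵥ) / N₀(v); the
Dis-increase ΔDis(v) = Dis_f(v)/max Dis_f − Dis_r(v)/max Dis_r
compares a vertex' normalized influence in the filtered (f) versus
reference (r) network. Bow-tie decomposition labels vertices as
LSCC / IN / OUT / OTHER, and Levene's test asks whether log2
fold-change variance differs between compartments.

## Worked example

```bash
python analysis/01_simulate.py        --seed 1 --out results
python analysis/03_filter_networks.py --seed 1 --out results
python analysis/04_pathway_enrichment.py --seed 1 --out results
```

The first script generates the study inputs (1800 vertices, 3900
edges, 137 pathways of mean size 47.8, an 84-tissue intensity matrix).
The second maps the two tag libraries onto the reference and prints
the filtered network sizes:

```
detected: normal 613, disease 614, union 648, symmetric difference 69
  network    variant  vertices  edges  wcc
reference          -      1800   3900    1
    union     strict       648    565  152
    union 1-extended      1535   3350    2
```

Strict filtering keeps roughly a third of the reference and fragments
it into 152 weak components; one extension step grows the network
2.37× and fuses it into 2 components — the reason both variants are
analyzed. The third script runs the enrichment tests; with the default
generator a pathway is planted with a threefold detection boost, and
the strict-mode output recovers it:

```
[strict_exact] 137 pathways tested, 1 with q<0.05; planted pathway PW_0001 ranks #1
pathway  k  K            p            q
PW_0001 42 42 5.513505e-19 7.553502e-17
```

`analysis/05_key_nodes.py` and `analysis/06_bowtie_expression.py`
complete the picture (key nodes whose mediator role emerges only after
filtering; Levene W = 5.53, p = 9.5e-4 for compartment-dependent
fold-change variance). The same stages are available as one CLI:

```bash
priornet -o run_dir --seed 1 all      # simulate -> filter -> enrich -> keynodes -> bowtie
priornet -o run_dir build-metabolic   # enzyme network from the reaction table
```

Every stage writes TSV outputs plus a `manifest.json` with the seed
and effective parameters; reruns with the same seed are byte-identical.

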