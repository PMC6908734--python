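# Methods

## Model

A pathway is a directed graph whose nodes house one or more genes and whose
edges carry a sign, activation or inhibition. Roles are structural:
**receptors** are nodes with no incoming signaling edges, **effectors**
nodes with no outgoing ones. A **circuit** is the subgraph of all directed
paths from any receptor to one effector; it is the unit whose activity is
reported, named `<pathway>:<effector label>`. One circuit aggregates all
receptors feeding an effector; a per-receptor decomposition is not
implemented. Membership is computed by reachability (a node belongs to the
circuit when some receptor reaches it and it reaches the effector), so
feedback loops lying on a receptor→effector walk are retained. Within a
circuit, in-edges of receptors and out-edges of the effector are dropped,
making receptors pure sources and the effector a pure sink.

Signal propagation assumes that transducing a signal requires the presence
of every protein along the chain and that more protein carries more signal,
with mRNA abundance as the proxy for protein availability. Each node's
value v ∈ [0,1] attenuates the incoming signal:

S = v · (1 − ∏(1 − s_act)) · ∏(1 − s_inh)

Receptors receive a constant incoming signal of 1, so S = v there. The
activation term treats parallel inputs as probabilistic alternatives (any
one suffices); the inhibition term attenuates multiplicatively. A
non-source node with only inhibitory inputs transmits nothing (the empty
activation product is 1, so the activation term is 0); only true
in-degree-0 nodes are treated as sources. All inputs in [0,1] imply all
signals in [0,1], and activity is weakly increasing in every node value on
activating routes.

### Cycles

The rule is recursive; on acyclic circuits one topological pass evaluates
it exactly. Circuits containing feedback are solved by Jacobi fixed-point
iteration started from zero signals (receptors at v), stopping when the
largest per-node change falls below `tol` (default 1e-6, cap 1000
iterations). For activation-only cycles the iteration is monotone
non-decreasing and bounded by 1, hence convergent; with mixed signs
convergence is checked at run time and a `NonConvergenceWarning` is raised
(the last iterate is still returned and flagged). Sweep-order independence
is verified empirically against Gauss–Seidel sweeps in the test suite.
Products are computed in linear space: all factors live in [0,1] and
circuits are far too shallow for underflow.

## Preprocessing

Input matrices are expected library-normalized (e.g. RMA or TMM upstream),
genes × samples, nonnegative. The chain to node values is:

1. log(x + 1);
2. truncation at the global 0.01/0.99 quantiles of the transformed matrix
   (a single pair of bounds for the whole matrix, not per gene or sample —
   the simplest reading, both quantiles configurable);
3. quantile normalization: every column's order statistics are replaced by
   the across-column mean order statistics; ties receive the mean of their
   rank positions;
4. min-max rescale to [0,1], global by default (one shared scale preserves
   cross-gene comparability inside the propagation rule; per-gene rescaling
   is available as an option);
5. gene→node aggregation, default the 90th percentile of a node's member
   genes (mirroring the probe→gene summarization convention; mean/min/max
   available). Nodes with no measured gene get the signal-neutral default
   0.5 and are logged — zeroing them would silently kill every circuit they
   sit on.

Probe-level input can be summarized first: per gene the 90th percentile of
its uniquely-mapping probes; probes mapping to several genes are discarded
unless they are a gene's only probes, in which case their median is used.
All percentiles use linear interpolation between order statistics.

### Frozen-reference transform

`ExpressionPreprocessor.fit` learns the truncation bounds, the reference
distribution and the rescale bounds; `transform` applies them frozen. The
transform is a single monotone **value** map — the pooled empirical CDF of
the fitted matrix (midpoint convention) composed with the quantile function
of the reference distribution — rather than a per-column rank map. This is
deliberate: under a rank map, perturbing one gene shifts the ranks, and
therefore the normalized values, of untouched genes. The value map
guarantees that a perturbation changes only the targeted rows after
normalization, preserving the "all other things equal" semantics of an in
silico knockout, at the price that transformed columns match the reference
order statistics only approximately. Classic self-contained quantile
normalization (exactly equalized column order statistics) is available as
`log_truncate_quantile_normalize`. Transformed values falling outside the
fitted scale (possible for over-expression) are clamped to [0,1].

Degenerate inputs: a matrix whose columns are all constant is passed
through unchanged with a warning; a constant column among varying ones is
an error; constant input to the rescaler maps to 0.5 with a warning.

## Perturbation simulation

Loss of function multiplies the target genes' expression by 0.01 (default)
in every sample; setting the value to 0 models total loss; factors > 1
model over-expression (clamped at the fitted ceiling). The perturbed matrix
re-enters the frozen preprocessing and propagation, and per-circuit log2
fold changes (pseudo-count 1e-10) are taken between mean activities;
per-sample activities are also returned. Fold change on mean activities was
chosen over mean per-sample fold change; both are derivable from the
exported per-sample matrices. The variant-interpreter scenario repeats this
per tissue — controls as given, cases simulated on every control sample —
and contrasts case vs control per circuit; a failing tissue is logged and
skipped without aborting the others. The LoF scan knocks down every gene of
the loaded pathway universe in turn and reports a gene × circuit impact
matrix plus a per-gene breadth count (circuits with |log2FC| above 0.5 by
default — a reporting knob only). Zygosity, variant filtering and VCF
handling are out of scope: the input is a gene list.

## Statistics

Per circuit, a two-sided Wilcoxon rank-sum (Mann–Whitney U) test compares
the two groups: exact null distribution when the smaller group has fewer
than 8 samples and no ties are present, otherwise the normal approximation
with continuity and tie correction. Circuits tied across all samples get
p = 1 (not NaN) to keep tables rectangular. Benjamini–Hochberg step-up
adjustment runs across all tested circuits. Direction (up/down/none) and
effect size are reported from group medians, independently of the two-sided
p-value; the unpaired rank-sum variant is the coherent choice for a
case/control design.

## Synthetic data

The fixture generator emulates the shape of real inputs, not their content:
random DAG topologies in a fixed topological order (edge probability 0.35,
12 nodes, 2 genes per node by default), an optional single feedback edge
for cycle tests, inhibition signs drawn at 0.2 per eligible edge with the
constraint that every non-source node keeps at least one activating input
(a node fed only by inhibitors transmits nothing and its circuits would be
dead by construction), and log-normal expression (gene baselines lognormal
with log-mean 4, log-sd 1; multiplicative noise log-sd 0.4; 20 samples by
default). Effect-injected fixtures duplicate the control columns and apply
the LoF factor to the target rows, which makes recovery contrasts
deterministic: untouched circuits are exact ties, touched ones fully
separated. Tissue panels share per-gene baselines and draw tissue-specific
noise plus a log-scale baseline shift (sd 0.5; 0 gives exchangeable
tissues). Gene IDs are synthetic (`G0001`…). The generator does not model
transcriptome covariance, batch structure, or real pathway topologies, so
passing tests demonstrate correctness of the machinery, not performance on
real data.

## Problem sizes and numerical choices

Calibration checks use ≥500 circuits assembled from ~170 ten-node pathways
with disjoint gene universes and 20+20 samples; oracle-equivalence checks
use 200 random DAG circuits of 5–15 nodes; recovery fixtures use 10+10
samples, one gene per node. Agreement tolerances: 1e-12 against the
brute-force evaluator (identical arithmetic, different traversal), 10×tol
for cyclic sweep-order comparisons. Tabular outputs print 6 significant
digits; fixture matrices 10, enough for byte-stable round trips. All
generators take explicit integer seeds and identical configurations produce
byte-identical files.

## Known limitations

- Mechanistic, not dynamic: no kinetics, no time course, no edge weights.
- mRNA-as-protein-proxy inherits all the usual caveats; the model also has
  no information about how a diseased tissue would transcriptionally react
  to the perturbation — simulated effects are first-instance impacts.
- Non-convergent mixed-sign cycles are flagged, not solved exactly.
- Circuit granularity is per effector; receptor-specific subcircuits are
  not separated.
- The frozen-reference transform trades exact column-wise quantile
  equalization for perturbation locality (see above).
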