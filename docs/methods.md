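# Methods

## Model and assumptions

phoskit treats phosphosite prediction as binary classification of
fixed-length sequence windows. The assumptions are those of the classic
window approach: (i) the signal that distinguishes a phosphosite lies in
the ±13 residues around the acceptor; (ii) it is expressible through the
composition of ordered residue pairs at small spacings (short linear
motifs such as SP, S×S, R-x-x-S); and (iii) no kinase identity is needed
— one model per acceptor type (S, T, Y) suffices. Sites of different
acceptor types are never mixed in one model.

### Window extraction

Windows have length 2n+1 (default n = 13 → 27). Out-of-sequence
positions are filled with the 21st letter `O`, which the encoders treat
as an ordinary alphabet symbol; a window therefore always yields the
same number of k-spaced pairs, L − k − 1 per spacing. Coordinates are
1-based and inclusive everywhere in the public interface.

### CKSAAP encoding

For spacing k, every ordered pair (window[i], window[i+k+1]) increments
one of 441 components. Components are ordered by spacing ascending, then
first residue, then second, with the alphabet `ACDEFGHIKLMNPQRSTVWYO`
(the 20 amino acids alphabetically, padding letter last); the published
form of the encoding does not fix the internal ordering, so this
bijection is our documented choice. Counts are raw occurrences, not
frequencies (a normalization toggle exists but defaults off, since
within one configuration L is constant and normalization is an affine
rescaling). Pairs are directional: AC ≠ CA. The central residue
participates in pairs; it is excluded only from the binary one-hot
encoding, where it is constant within a model and carries no
information.

### Negative selection and balanced replicates

Negative candidates are residues of the model's acceptor type lying
strictly more than d = 50 residues from **every** annotated site of the
protein, regardless of that site's type. "More than" is implemented as
|Δ| > d (the reading that maximally separates negatives from positives);
d is configurable. Negatives are pooled across proteins before sampling
— the simplest defensible reading where the data give no reason to
sample per protein. Each of the R = 10 replicates draws uniformly
without replacement within the draw, independently across replicates;
per-replicate integer seeds are derived from the master seed and
recorded on each `BalancedSet`, so any replicate can be rebuilt
byte-identically (`rebuild_replicate`).

Sequences may contain the ambiguity letters X/B/Z/U on input; any window
containing one is dropped with a logged warning, since the encoding
alphabet has no slot for them. Redundancy reduction (e.g. clustering at
40 % identity) is deliberately out of scope: the builder assumes
pre-deduplicated input and `evaluate_independent` only warns on
provenance overlap.

### Information-Gain ranking

IG(X;Y) = H(X) − H(X|Y) with base-2 logarithms (the base cancels from
the ranking). Each distinct integer count is its own category — counts
in a 27-mer are small integers, so binning would only blur the
statistic. Ties are broken by ascending feature index for
reproducibility. An exact vectorized bincount path computes per-column
IG for the full 2646-feature matrix; the scalar
`entropy`/`conditional_entropy`/`information_gain` functions are the
reference implementation and the fallback for non-integer data. Ranking
is reporting-only by default: consistent with the finding that pruning
features brings no benefit to the RBF SVM, the final models always use
the full vector. When several replicates are ranked, per-replicate
tables and a mean-rank summary are both available (`mean_rank`).

### SVM ensemble

Per replicate, a soft-margin RBF SVM is selected by exhaustive grid
search over C, γ ∈ {2⁻⁷, …, 2⁸} (256 combinations), scored by stratified
5-fold CV accuracy — accuracy because it is the headline metric of this
problem setting; the scorer is swappable. All grid points share one fold
assignment derived from the seed; ties go to smaller C, then smaller γ.
The search precomputes the pairwise squared-distance matrix once and
evaluates each grid point with a precomputed kernel, which is
mathematically identical to refitting with the RBF kernel but avoids
recomputing it 1280 times. Selection is per replicate (the modal choice
is logged). The final per-replicate model adds Platt-style sigmoid
calibration fitted on cross-validated decision values, so each model
emits probabilities; the quadratic program itself is solved by libsvm
via scikit-learn. Ensemble prediction is the arithmetic mean of the
replicate probabilities, thresholded inclusively at 0.5.

### Evaluation

Sn, Sp, Ac are percentages; MCC uses its standard product formula with
the convention MCC = 0 when any marginal is zero. ROC sweeps all
distinct scores (ties grouped), AUC is the trapezoid area and equals the
Mann–Whitney concordance probability — the test suite checks this
identity against an independent rank-statistic computation.
Cross-validation folds are stratified; the summary is the unweighted
mean over folds.

## The synthetic-data generator

`simulate` emulates the structure of curated phosphosite corpora:
proteins of uniform random length 100–500 over a uniform (or supplied)
residue composition; a Poisson(2) number of annotated sites per protein
chosen among existing acceptor residues; and short motifs planted around
each annotated site with per-motif probabilities. Defaults: SP 0.5,
S×S 0.35, R××S 0.35 for serine (TP/T×P/T×××T and D×Y/Y××P for T and Y) —
roughly the coverage of the dominant proline-directed, acidophilic and
basophilic kinase motif classes in real data. When a motif contains the
acceptor letter, its first occurrence is aligned to the site (so R××S
puts the arginine three residues upstream of the phosphoacceptor);
acceptor-free motifs are planted immediately downstream. Planting never
overwrites an annotated acceptor residue. Ground truth (which motif was
planted where) is emitted alongside the FASTA and annotation TSV, and
identical seeds give byte-identical files.

What the generator does **not** emulate: realistic amino-acid
composition bias, disorder tracts, homologous proteins (so redundancy
reduction is untested here), kinase families, and position-specific
preferences beyond exact planted pairs. Passing tests therefore show
that the pipeline recovers pair-composition signal under its own
assumptions, not that it reaches any particular accuracy on curated
phosphoproteome data.

One subtlety is real and intentional: even with planting disabled, the
amount of `O` padding carries a little class signal, because positives
may sit near protein termini while terminal negatives are depleted by
the 50-residue exclusion around sites. This mirrors the observation on
real data that including the padding letter changes performance
slightly. The null-generator invariant (no feature informative) is
therefore asserted on padding-free windows, where the classes are
exactly exchangeable.

## Problem sizes and numerical choices

The end-to-end checks train on 150 simulated proteins (~300 serine
positives, 10 replicates) and test on 120 held-out proteins, with the
grid restricted to C ∈ {2⁻¹…2²}, γ ∈ {2⁻⁸…2⁻⁶} — a neighbourhood of the
optimum that the full 256-point search selects on this data (modal
choice (2, 2⁻⁷)); the full grid protocol is exercised separately on a
small toy set. Under these conditions the 3-seed median held-out AUC of
the serine ensemble is ≈ 0.81, and the planted SP pair ranks in the top
decile of the IG ranking.

Degenerate inputs fail loudly: empty FASTA, annotation/sequence
mismatches, windows shorter than k+2, single-class training sets,
negative pools smaller than the positive count, and single-class ROC
input all raise with specific messages. IG values within 1e−9 below
zero are clipped to 0 (floating-point dust); anything lower raises.
Model archives carry a format stamp and the package version and refuse
to load across versions.
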