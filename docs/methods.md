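# Methods

## Model and assumptions

The framework rests on two assumptions. First, direct information transfer
requires a structural connection: two regions communicate directly only if a
white-matter edge links them, so all communication channels are paths on the
structural connectome (SC). Second, the amount of communication between
structurally connected regions is measured by the functional coupling of
their activity, quantified as pairwise mutual information (MI, bits) between
their time series. The SC is weighted by mean streamline length in
millimeters and used unthresholded and unbinarized; channels are the
minimum-total-length (fiber-length) shortest paths, minimized directly on
the lengths — no inverse transform, since shorter fibers mean closer
regions. An off-diagonal zero in the SC encodes an absent connection, never
a zero-length fiber.

## MI estimation

Regional time series are z-scored per region using the population standard
deviation (dividing by T; the difference from the sample SD is immaterial at
realistic series lengths but is fixed for reproducibility), then discretized
on a uniform grid over the z-score axis: default bin width 0.5 SD spanning
[−3.5, 3.5], i.e. 14 bins. Bins are half-open [lo, hi) with the last bin
closed — a declared convention, as either choice is defensible. Values
outside the range are clipped into the boundary bins rather than dropped,
preserving T (the range covers >99.9% of Gaussian mass, so clipping is
rare). Widths that do not evenly divide the 7-SD range (0.75 and 2, both
part of the sensitivity analysis) are handled by truncating the top bin at
the upper bound.

MI is the plug-in (maximum-likelihood) estimate
H(X) + H(Y) − H(X, Y) in bits, computed once per unordered pair; no bias
correction is applied. The diagonal of the FC stores each region's binned
entropy H(i) and is excluded from nodal strengths and path scores. Repeat
acquisitions (e.g. the two phase-encoding runs of a session) are averaged
elementwise; `bin_sensitivity` reports the cross-width correlation of
upper-triangle MI values as the robustness summary.

A quantitative caveat, verified against numerical integration of the exact
binned bivariate-Gaussian distribution: discretization at 0.5-SD bins loses
information, so the estimator's population target lies below the continuous
Gaussian value −½log₂(1−ρ²) — by ~0.003 bits at ρ=0.3, ~0.016 at ρ=0.6 and
~0.115 at ρ=0.9. At T=10⁵ the estimate is within ~0.003 bits of the exact
binned value; tests therefore compare against the binned oracle at strong
coupling and against the continuous formula only where the loss is small.

## Shortest paths

All-pairs geodesics are computed by an explicit Dijkstra with a
lexicographic (length, hops, node sequence) key, because the downstream
scores depend on the exact node sequence and ties must resolve
deterministically: among equal-length paths the fewest hops win, then the
lexicographically smallest node-index sequence as seen from the
lower-indexed endpoint. Each unordered pair is solved once from its
lower-indexed endpoint and the opposite direction is defined as the
reversal — this guarantees that the s→t and t→s sequences are mutual
reverses, which independent per-direction lexicographic tie-breaking would
not (lexicographic minimality is not preserved under reversal). Disconnected
pairs carry a marker, not an exception. Structurally adjacent pairs whose
geodesic is nevertheless multi-edge (possible when fiber lengths violate the
triangle inequality) are treated by their computed geodesic; the *direct*
regime applies only to genuinely single-edge geodesics.

## PPS and regimes

PPS sums, over every post-source path node i ∈ {K₁, …, K_m, T}, the
difference MI(S;K₁) − MI(S;i): every summand is anchored at the first hop,
exactly as the defining equation is printed (the K₁ term is identically
zero). An alternative telescoping reading — consecutive differences, which
collapse to MI(S;K₁) − MI(S;T) — is available as a non-default mode
(`mode="telescoping"`); the two agree on 2-edge paths. PPS is undefined for
single-edge geodesics and is generally nonsymmetric.

Regime boundaries default to (−0.04, 0.07) bits, the [5, 95] percentiles of
the within-default-mode-network PPS distribution at rest; the estimation
procedure is exposed (`estimate_boundaries`) for any reference network or
pooled value vector (pooling across subjects is the caller's
concatenation), requiring at least 20 defined values for a stable
percentile. The relay interval is closed at both ends — the endpoints'
membership is unspecified by the defining procedure, and a closed interval
keeps exact-zero PPS in relay.

## PBS and nodal broadcasting

Raw PBS is the negative log₂ of the product, over path nodes excluding the
target, of the path-edge MI divided by the node's structurally masked
strength W_i = Σ_{j:SC(i,j)>0} MI(i,j). The full W_i is used for every node,
as the defining formula states; the classical search-information variant
that subtracts the arrival edge's MI at intermediate nodes is available as
`mode="exclude_arrival"`. Since each path edge is structural, its MI is a
term of its tail node's W_i, every ratio is ≤ 1 and raw PBS ≥ 0. PBS is
defined for direct (single-edge) paths. A zero-MI path edge yields an
infinite PBS marker, excluded from nodal sums with a logged count. Reported
PBS is raw divided by the geodesic length in millimeters (bits/mm), removing
the bias of longer paths accumulating more terms.

Orientation convention: `PBS[s][t]` scores the path s→t, so
WBS_sender(k) = Σ_t PBS[k][t] and WBS_receiver(k) = Σ_s PBS[s][k] — the
subscript order of the defining sums is ambiguous in prose, so the
orientation is fixed by the sender/receiver semantics of the names. WBS
sums are restricted to pairs carrying the requested regime label; the
symmetric WBS is exactly the elementwise mean of sender and receiver.
Rankings (`top_regions`) sort by symmetric WBS, ties broken by region index.

## Stratification

Regime-by-network tables count ordered (source network, target network)
pairs — the scores are nonsymmetric, so ordered pairs are the primitive —
and report percentages of each regime's defined paths (summing to 100 per
regime); the unordered within/between reading pools reciprocal cells on
request. Sender−receiver asymmetry is emitted as per-node difference
vectors with median/IQR summaries; no hypothesis testing is performed — the
vectors are exactly what an external rank test would consume.

## Synthetic data

The structural generator is a random geometric graph: regions placed
uniformly in a 100-mm box, connected within a radius (default 60 mm), with
Euclidean distance as the millimeter edge length. Euclidean lengths are
metric, so direct edges are geodesics and fixtures are hand-verifiable; a
multiplicative `length_noise` mode breaks metricity to exercise multi-edge
geodesics between adjacent regions. The functional generator draws
zero-mean Gaussian series with a prescribed correlation matrix (Cholesky of
the ridged correlation), for which MI is known in closed form
(−½log₂(1−ρ²)); Gaussian chains with hop correlation ρ give
corr(S, K_j) = ρʲ and satisfy the data processing inequality in population.
All generators are fully determined by an integer seed through NumPy's
`default_rng` (PCG64); this RNG contract is public API.

What the generators do *not* emulate: hemodynamic convolution and
autocorrelation of BOLD, scanner noise and motion artifacts, tractography
biases (length-dependent streamline attrition, gyral bias), or realistic
degree/strength distributions of human connectomes. Passing tests therefore
demonstrate correctness of the measurements and their invariants on
known-truth inputs, not empirical claims about human brain data.

## Numerical choices and problem sizes

Matrix symmetry is validated to 1e-9; round-trip I/O uses 17 significant
digits (exact for doubles). MI uses exact bincount histograms; tiny negative
MI round-off is clamped to zero. Undefined path-score entries are NaN,
infinite PBS is inf, and both are excluded (and counted) in aggregates.
Default test and acceptance problem sizes — 8-node graphs for exhaustive
path enumeration, ≤8-node fixtures for formula fidelity, T=10⁵ for
estimator accuracy, 100 seeds × T=5000 for chain behavior, a 40-region
synthetic study at T=2000 — are chosen so every brute-force oracle remains
exactly enumerable while estimator noise stays well inside the asserted
tolerances.

## Known limitations

Boundaries calibrated on one reference network are not universal; other
null models would shift them. The plug-in MI estimator is biased upward at
small T and the binning loses information at strong coupling (quantified
above). Communication is assessed only along single shortest paths — path
ensembles, navigation and diffusion-style models are out of scope. The
packaged 374-region parcellation table uses realistic per-network region
counts but a constructed (synthetic) region-to-network assignment, suitable
for defaults and demonstrations, not for anatomical inference.
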