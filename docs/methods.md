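# Methods

This note documents the models and procedures rhythmkit implements, the
parameters that matter, the numerical choices made where a convention was
genuinely open, what the synthetic generators do and do not emulate, and the
known limitations of each method. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

The analysis primitive is the element onset: the start time, in seconds, of
a syllable, call or click. A sequence is an ordered list of onsets (an
`ElementSequence`) or, equivalently up to a time shift, its inter-onset
intervals (an `IOISequence`, IOIᵢ = onsetᵢ₊₁ − onsetᵢ, strictly positive).
Every statistic in the package is invariant under time translation, so
sequences reconstructed from IOIs are anchored at t = 0 without loss.
Offsets (element end times) are carried through I/O for provenance but used
by no statistic: intervals are onset-to-onset, comprising the element and
the following gap. Element labels likewise ride along unused.

Label files are parsed leniently by default (rows sorted by onset with a
warning) because hand-edited field exports are routinely out of order;
`strict=True` turns ordering violations into errors. IOI tables are
long-format (species, individual, sequence id, IOI) with a configurable
column mapping and an `s`/`ms` unit switch, since exported spreadsheets vary.

## IOI statistics

For a set of n IOIs with sample mean x̄ and standard deviation s (the (n−1)
denominator — the small-sample correction below presupposes the sample
estimator):

    CV  = s / x̄            CV* = (1 + 1/(4n)) · CV

CV* corrects the downward bias of CV at small n; n is always the number of
IOIs in the set being summarized (pooled n for a dataset-level value,
per-sequence n for sequence-level values). A dataset summary reports both
the pooled CV* ("overall") and the mean of per-sequence CV* ("sequences");
internally consistent but mutually different sequences produce a small
per-sequence value and a large pooled one, so the gap between the two
indicates likely differences between sequences and individuals.

The normalized Pairwise Variability Index of m IOIs is

    nPVI = 100/(m−1) · Σₖ |IOIₖ − IOIₖ₊₁| / ((IOIₖ + IOIₖ₊₁)/2).

It is exactly zero iff all adjacent pairs are equal and below 200 for
positive intervals. The dataset-level "overall" nPVI averages the adjacent-
pair contributions of all sequences but skips the pair that straddles each
sequence boundary: those two intervals are not adjacent in time, and
including them would leak between-sequence tempo differences into a
within-sequence index. The number of excluded pairs is recorded on the
summary so the convention is visible in output.

The "exact beat frequency" of a sequence under IOI analysis is 1/mean(IOI),
in Hz.

## Fourier beat detection

Onsets are rasterized to a 0/1 series at resolution dt (default 5 ms, i.e. a
200 Hz sampling rate and a 0–100 Hz analysis band — adequate for bird song,
bat social calls and whale clicks alike; extreme signals need a different
dt, which trades off against frequency resolution). The first onset maps to
sample 0 and each onset to its *nearest* bin (rounding halves the worst-case
quantization error versus flooring; which convention the field's prior
analyses used is not recoverable, so beat frequencies from other
implementations may differ within one bin). Two onsets landing in one bin
collapse to a single 1 and are counted as collisions; a dt coarser than the
smallest IOI triggers a warning. The raster starts and ends with an event by
construction.

The spectrum uses the 1/N discrete transform convention,
X(f) = (1/N)·Σ x(n)e^(−j2πfn/N), with no windowing or zero-padding. For a
0/1 raster the DC amplitude X(0) = n_events/N equals the time-domain mean
and upper-bounds every other magnitude, so it serves as an internal
reference. The best beat is the frequency of maximum magnitude in
(0, f_max], DC excluded, ties to the lowest frequency; a flat spectrum
(every sample an event) is flagged "no beat". Frequency resolution is the
bin spacing 1/(N·dt); signals under ~1 s get a warning because the spacing
then rivals typical beat frequencies — the method's main failure mode on
short sequences.

Goodness of fit:

    GOF  = |P_best| / |P₀|          nGOF = GOF / L

GOF is the share of the internal reference carried by the selected beat
(0–1). The length normalization L is the **number of samples N** by default.
The alternative reading of "sampling length" — duration in seconds — is
available as `length_units="seconds"`; samples is the default because it is
the only reading consistent with the magnitudes this normalization is known
to produce on real datasets (e.g. GOF of a few tenths paired with nGOF of
order 10⁻⁵ on ~100 s click trains implies L ≈ 2×10⁴ = samples, not ≈ 100).
The cost is that nGOF is not dt-invariant; comparisons across studies must
therefore fix dt, which the report's config snapshot makes explicit. nGOF in
either unit preserves the magnitude ordering across datasets of very
different lengths.

## Generate-and-test (GAT)

Candidate frequencies run over an inclusive grid, default 2–100 Hz in
0.01 Hz steps, generated index-based (f = f_min + k·df) to avoid cumulative
floating-point drift. Each candidate defines the isochronous grid
{t₀ + k/f} anchored at the first onset; each onset's deviation is its
distance to the nearest grid point (≤ half a period), and

    FRMSD = RMSD · f

expresses the RMS deviation as a fraction of the cycle. Two conventions
circulate for "frequency-normalized" RMSD; rmsd·f is the default because it
is the one that is a cycle fraction and whose minimization favours the
slowest beat among harmonically equivalent fits (rmsd/f is available via
`convention="rmsd_over_f"`). The best beat is the global FRMSD minimum with
ties resolved to the slowest frequency — if every onset sits on the grid of
f, it also sits on the grid of every harmonic k·f with identical zero score,
and the tie rule returns the fundamental.

Two numerical choices deserve note:

* **Tie tolerance.** Minima within 10⁻¹⁰ (dimensionless) are treated as
  exact ties, so rounding noise cannot promote a harmonic over the
  fundamental.
* **Subharmonic refinement** (`prefer_fundamental=True`, default). When the
  winning score is an exact fit but the fundamental period is not
  representable on the 0.01 Hz grid (e.g. 0.3 s IOIs: 3.333… Hz is between
  grid points while its harmonic 10 Hz fits with exactly zero deviation),
  the reported beat would otherwise be the representable harmonic. Exact-tie
  winners are therefore refined to their slowest exactly-fitting integer
  subharmonic, allowing an off-grid frequency in this one case. Disabling
  the flag restores the strict grid-minimum contract.

Phase is anchored at the first onset by default — the simplest reading of
testing against generated isochronous sequences; `optimize_phase=True`
minimizes RMSD over the grid phase per candidate instead (never worse,
rarely different for near-isochronous data, slower).

A limitation worth stating explicitly, because the test suite encodes it:
an anchored single-beat fit recovers tempo from *bounded* interval jitter
(a jittered comb), but not from heavy i.i.d. interval noise. Under i.i.d.
noise the onset phase performs a random walk that wraps around the cycle, so
for long noisy sequences the FRMSD curve flattens toward the
uniform-phase value 1/√12 ≈ 0.289 at every frequency and its minimum
scatters across the window. The IOI mean remains a consistent tempo
estimator in that regime — one reason the decision cascade keeps IOI
analysis alongside GAT. GAT likewise fits a single frequency and is
unsuitable for tempo-changing sequences.

## Recurrence matrices

M[i,j] = |IOIᵢ − IOIⱼ| over all pairs, both axes in sequential order:
symmetric, zero-diagonal, scale-covariant. Rendered with white = 0 and
darker = larger (grayscale), the color scale per-plot (min–max of that
matrix) by default — equal shades are therefore *not* comparable across
plots, and the rendered figure carries that caveat; pass a shared `vmax`
for cross-plot comparison. Matrices are dense; sequences here are at most a
few hundred IOIs. Interpretation is visual by design — no automated pattern
detection is attempted.

## Beat clustering

Per-sequence beat frequencies within an individual are clustered
agglomeratively with group-average (UPGMA) linkage on 1-D Euclidean
distances and cut at a dissimilarity threshold, default 0.05, applied to raw
Hz distances. That literal threshold is startlingly tight for Hz-scale data
(it merges only beats within a few hundredths of a Hz); because the
convention behind published uses of this cut is ambiguous, the threshold is
a config key and `normalize=True` divides frequencies by their mean first,
making 0.05 a 5% relative-tempo cut. The acceptance script uses the
normalized variant for its stand-in clustering summary, as the raw cut
yields near-singleton clusters on realistically dispersed beats. The
largest-cluster share (largest cluster size / sequences) summarizes tempo
concentration per individual; individuals with fewer than two sequences are
excluded with a warning.

## Synthetic data

All generators require an explicit seed (no global state) and emit strictly
positive IOIs. Three canonical datasets mirror standard validation practice:

1. **Isochronous**: onsets at k·IOI for IOI ∈ {0.1, 0.3, 0.5} s. Every
   variability index must be zero and all three beat methods must recover
   10 / 3.33 / 2 Hz within their resolutions.
2. **Uniform aperiodic control**: 10 sequences × 100 elements, IOIs i.i.d.
   U(0, 1) (exact zeros redrawn). Carries no periodicity; the cascade must
   recommend nothing.
3. **Gaussian**: 10 × 100, IOIs i.i.d. N(mean, sd) for (1, 0.5), (0.2, 0.1),
   (0.1, 0.05), non-positive draws redrawn. The rejection truncates the left
   tail and biases the realized mean upward, most visibly at sd/mean = 0.5;
   the truncated-normal mean is the oracle for that bias in the tests.

The **jittered comb** (IOIs = base·(1 + U(−j, +j)), j < 0.5) bridges cases 1
and 2 and underlies the goodness-of-fit validation: along a jitter sweep the
median nGOF decreases, the median FRMSD increases, and the two are strongly
negatively rank-correlated — two independent goodness-of-fit values agreeing
on ordering.

**Species stand-ins** (`species_standin`) are synthetic surrogates for three
published bioacoustic datasets (monosyllabic short bat isolation-call bouts,
multisyllabic medium bat isolation calls, very long sperm whale click
trains) whose raw interval data is not redistributed here. They are built
from published summary statistics only: sequence counts per individual,
element-count mean/SD/range, pooled mean IOI, pooled and per-sequence CV,
and mean nPVI. Each sequence draws a tempo multiplier N(1, cv_between) with
cv_between = √(cv_overall² − cv_within²), then IOIs from a stationary AR(1)
Gaussian series whose lag-1 correlation is set so the expected nPVI matches
the published mean (adjacent correlated Gaussians give
nPVI ≈ 112.8·CV·√(1−ρ); smooth within-train drift ⇒ ρ > 0 ⇒ low nPVI,
alternation ⇒ ρ < 0). The stand-ins reproduce the gross statistics — IOI
scale, CV structure, nPVI, sequence-length distribution, and hence the
nGOF magnitude ordering and prominent beat categories — but none of the real
data's microstructure (syllable-type alternation, feeding-buzz edges,
individual signatures). Tests passing on stand-ins therefore validate the
machinery and scale behavior, not fine-grained reproduction of the original
recordings; the per-sequence reproduction tests run only when the original
IOI table is supplied under `data/`.

## Decision cascade

The method recommendation formalizes a qualitative workflow, so its
thresholds are package choices, always echoed in the output:

| key | default | role |
|---|---|---|
| `npvi_aperiodic` | 60 | mean nPVI at/above ⇒ aperiodic |
| `cv_periodic_max` | 0.5 | per-sequence CV* at/above ⇒ aperiodic |
| `npvi_strict_isochrony` | 15 | below ⇒ strict isochrony |
| `npvi_isochrony_max` | 40 | middle band still isochrony-compatible if CV* < `cv_isochrony_max` (0.3) |
| `npvi_individual` | 30 | at/above ⇒ individual differences likely |
| `cv_gap_max` | 0.1 | pooled − per-sequence CV* strictly above ⇒ individual differences likely |
| `fft_min_duration` | 1 s | median sequence duration below ⇒ FFT inadequate |

Periodicity requires a unimodal IOI distribution (assessed by a smoothed
histogram mode count — a descriptive stand-in for the visual judgement, not
a dip test) plus nPVI and CV below the aperiodic cutoffs. Isochrony follows
the nPVI bands. Method choice: likely individual differences route to GAT
(a pooled IOI mean oversimplifies); otherwise IOI + FFT when sequences are
long enough for the FFT's frequency resolution, IOI + GAT when not;
tempo-changing sequences (flagged by a monotone relative IOI drift beyond
`tempo_slope_max`) route away from GAT toward recurrence inspection.
"Unclear" verdicts are legal outputs, and the rationale lists every rule
that fired. The defaults reproduce the three published dataset routings
(short variable bat bouts → GAT; both long regular datasets → IOI/FFT) when
fed the published summary rows.

## Degenerate inputs and tolerances

Exactly-constant IOI sets score exactly 0 on CV and nPVI (the two-pass
variance otherwise leaves ~10⁻¹⁷ residue, handled explicitly); IOIs derived
from a non-dyadic onset lattice (0.1·k) wobble at float precision, so
zero-identities on derived intervals hold to 10⁻⁹. CSV round trips preserve
IOIs bit-exactly (17-significant-digit output, round-trip float parsing).
Spectrum values agree with a direct O(N²) transform to 10⁻⁹ relative; GAT
scoring agrees with explicit grid enumeration to 10⁻¹²; UPGMA partitions
match a naive O(n³) agglomeration exactly. Problem sizes in the test suite
and acceptance script (100-element sequences, 50 replicates per jitter
level, full 9 801-point GAT grids, stand-ins at published sequence counts)
were chosen as the smallest that exercise each regime convincingly; the
whole suite runs in seconds.
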