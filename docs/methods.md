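# Methods

`mirbact` implements a pipeline for proposing bacterial targets of host
fecal miRNAs in shotgun metagenomic reads, together with a synthetic-data
module that plants ground truth for every stage. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## Candidate-site screening

A read is a candidate target of a miRNA when the miRNA's
target-complementary sequence fits inside the read within at most
`max_edits` (default 3) mismatches or indels. The alignment is semi-global
("fit"): the full pattern must be embedded in the read, with free end gaps
on the read only. This choice — rather than a local alignment — means the
edit budget always refers to the whole miRNA; a local aligner could hide
edits by clipping miRNA ends, making a 3-edit budget meaningless. When the
pattern extends past a read end, the overhanging pattern bases are charged
as deletions, so partially covered sites are admitted exactly when the
overlap is at least (pattern length − max_edits).

Since identical strands do not hybridize, the pattern is by default the
reverse complement of the miRNA in DNA form, scanned against both read
orientations (`pattern="identity"` is available for the literal
screen-with-the-miRNA reading). Note that under both-orientation scanning
the two conventions see the same set of molecules — a read whose reverse
complement contains the pattern is reported with `orientation="revcomp"` —
so the convention chiefly fixes which strand the reported window and
`target_rna` refer to, keeping the duplex stage self-consistent.

Ties in the DP are broken deterministically: minimum cost, then leftmost
window start, then shortest window. One best site per (read, orientation)
is reported, because downstream hit counting is per read, not per site.
The scalar DP (O(pattern × read), with window and alignment trace) is
paired with a vectorised batch variant used for throughput; the two are
property-tested equal, and both are tested against an exhaustive
substring-Levenshtein oracle and an independent library implementation
(edlib, infix mode).

## Duplex free energy

Candidate windows are scored with a duplex-only nearest-neighbor model:
the minimum over all antiparallel-monotone intermolecular pairings
(Watson–Crick plus GU wobble) of

    dG = duplex_init + Σ stacks + Σ loop penalties + terminal penalties.

Stacking energies are the published Turner-2004 values (kcal/mol, 37 °C)
embedded as data; duplex initiation is +4.09 and the terminal AU/GU
penalty +0.45, the values printed in the parameter literature (ViennaRNA
rounds these to 4.10/0.50, which the cross-check test tolerates). Bulge
and internal-loop penalties use an affine approximation — bulge(n) = 3.3 +
0.5 n; internal(n₁,n₂) = 1.7 + 0.4 (n₁+n₂) + 0.3 |n₁−n₂| — nondecreasing
in length and symmetric between strands; no stacking bonus is applied
across a loop. Loop spans are capped at 10 nt per strand, which bounds the
DP cost and exceeds anything relevant at miRNA scale. All constants can be
overridden from a TSV parameter file.

Two modeling decisions deserve emphasis. First, target accessibility (the
energetic cost of opening intramolecular structure around the site, as
RNAup computes) is deliberately out of scope: the model scores the
intermolecular duplex only, RNAduplex-style, and the −20.0 kcal/mol hit
gate is therefore model-relative rather than an RNAup-comparable number.
Second, "no duplex" is reported when no pairing achieves dG < 0; a
positive-energy duplex is worse than no interaction and is never a hit
anyway, since the gate sits far below zero.

The DP is verified against brute-force enumeration of all pairings for
short sequences, against the closed-form stacking sum for perfect helices,
and against ViennaRNA `duplexfold` for perfect complements. A useful
guarantee, asserted by scanning generated cases: any perfect-complement
helix of ≥ 19 pairs with GC fraction ≥ 0.5 clears the −20.0 gate — this is
what makes GC-rich planted sites deterministic hits in the synthetic
studies. Hit calling is inclusive at the threshold (dG ≤ −20.0).

## Taxonomic classification

Hit-bearing read pairs are assigned to taxa with a k-mer LCA classifier.
The database maps every canonical k-mer (k = 21, lexicographic min of
k-mer and reverse complement) of the labeled genomes to the lowest common
ancestor of all leaves containing it. A pair is classified to the node
whose root-to-leaf path carries the greatest total mapped-k-mer weight;
among equally weighted paths the shallowest node wins (so a pair whose
evidence sits entirely on a shared segment is assigned to the sisters'
parent, not an arbitrary leaf), with remaining ties broken by smallest
node id. Confidence is the fraction of the pair's k-mers — mapped or not —
inside the clade of the assigned node; below the threshold (default 0.1)
the label moves rootward until it qualifies or the pair is unclassified.
Unlike Kraken 2 this stand-in uses plain k-mers rather than minimizers and
spaced seeds; at desk scale the label semantics are identical, and the
pipeline depends only on read→taxon labels with a confidence knob.
Classification operates on pairs (both mates pooled); a per-read path is
available by constructing a pair with one mate.

## Filters and hit aggregation

Every retention rule is data in the configuration, at its study default:
miRNAs need ≥ 10 reads in ≥ 10% of samples of at least one group; taxa
need ≥ 100 reads likewise; fecal samples need ≥ 1000 miRNA and ≥ 100 000
classified metagenomic reads; mucosal samples need ≥ 2000 of each; the
screen considers samples with ≥ 1000 total miRNA reads; displayed taxa
need ≥ 10 hits for at least one miRNA. "10% of samples" is computed as
ceil(0.10 n) — the conservative reading, with floor available — and sample
filters run before feature filters. All boundaries are inclusive exactly
as written (999 fecal miRNA reads fail, 1000 pass).

Hits are aggregated per (sample, miRNA, taxon) with each mate of a pair
counted independently; unclassified reads contribute nothing; hit counts
are raw (no depth normalisation). Species-level labels can be rolled up to
genus through the taxonomy. The per-sample median and IQR of hit totals
are reported alongside the table.

## Association (CLR → sPLS → CIM → permutation FDR)

Count matrices receive a pseudocount of 1 and a centered log-ratio
transform. Sparse PLS follows the mixOmics regression-mode formulation:
columns are standardised; per component the singular directions of XᵀY
are iterated with hard-thresholding to the `keep` largest-|·| loadings and
soft shrinkage at the cut value (ties at the cut broken by feature index);
both blocks are deflated on the X-score. Non-convergence within `max_iter`
is recorded as a warning on the model, not an error — under a global null
the alternating iteration can cycle between near-equivalent sparse
directions, which is informative rather than fatal. The implementation is
cross-checked against R mixOmics on simulated data (identical supports,
loading cosine and score correlation > 0.999).

The CIM similarity matrix is C_X · C_Yᵀ, where C_X and C_Y hold Pearson
correlations of each feature with the X-scores. `ncomp` and the sparsity
levels are not dictated by the method; defaults are ncomp = 2 and keepX =
keepY = 20, matching the scale at which such maps are usually displayed,
and all are configurable.

P-values come from shuffling the miRNA rows of C_X and recomputing the CIM
(default 100 000 iterations at study scale; the desk-scale analyses use
1000): p = (# permuted |CIM| ≥ observed |CIM|) / n_iter, two-sided on
magnitudes since CIM entries are signed (a one-sided mode exists). No
pseudo-observation is added — raw counts over iterations, with a
`smoothed` (count+1)/(n+1) option. Benjamini–Hochberg adjustment is
applied over all entries (re-implemented; cross-checked against
statsmodels). Because each row's permutation distribution has only as
many distinct values as there are miRNA features, attainable p-values are
discrete; calibration checks should use enough features (the studies use
100) for the p < 0.05 fraction to be meaningful.

## Protein context and triples

MFE-passing pairs are placed in protein space with a toy-scale translated
search: six-frame translation (stop codons split frames into independently
searched segments), exact 4-aa seed matches, ungapped x-drop extension
under BLOSUM62, one best alignment per protein. Extension is ungapped —
reads are short and the scientifically active surface is the filter and
best-hit logic, not aligner parity; a gapped mode is a noted extension
point. Identity is matches over aligned columns; query coverage is aligned
amino acids × 3 over read length in nucleotides (an amino-acid basis is
configurable — the rule's basis is genuinely ambiguous). Hits need ≥ 90%
identity and ≥ 80% coverage; at most 25 per read are kept, by bitscore
(λ = 0.3176, K = 0.134, ungapped BLOSUM62 constants; since bitscore is an
affine transform of the raw score, the constants cannot change any
ranking or best-hit outcome).

The pair's final hit is the highest-bitscore member of the two mates'
hit-list intersection by protein id (per-protein score = max over mates,
which preserves ranking when both mates hit the same protein); bitscore
ties are broken uniformly at random under the run seed; an empty
intersection falls back to the maximum over the union; two empty lists
yield no protein label. A pair contributes one (miRNA, protein, taxon)
triple per passing miRNA only when all three labels exist. Triple count
matrices are summarised by PCA (scikit-learn, columns centered, components
sign-fixed so the largest-|loading| entry is positive).

## Synthetic data and what the studies show

The generator is a pure function of (parameters, seed); each generator
draws from its own fixed sub-stream of the master seed so stages can be
re-run independently. It emulates: leaf genomes i.i.d. uniform over ACGT
with optional segments copied between sister leaves; non-overlapping ORFs
(60–300 codons, ATG start, standard code) whose translations form the
proteome; planted sites that are exact reverse complements of miRNAs with
a controlled number of edits, on the forward strand only (read sampling
covers both strands, so orientation handling is still exercised);
paired-end reads drawn multinomially from taxon abundances with uniform
fragment placement and per-base substitution errors; and miRNA/taxon count
matrices sharing sparse latent factors (standard-normal scores, log-scale
loadings of magnitude 2 on supports of 3 features, feature noise SD 0.5,
multinomial depth 10⁵ — variation of a couple of log-units across samples,
the scale real taxa show).

Study dimensions are desk-scale: 4 taxa × 10-kb genomes, 6 GC-rich 22-nt
miRNAs, 5 sites per taxon, 2000 pairs per sample, 2 samples; association
studies use 100 samples (recovery) and 50 samples × 100 miRNAs × 30 taxa
(calibration). These sizes exercise every code path with meaningful
counts while a full validation run completes in seconds to minutes.

The exact-recovery result (recall = precision = 1 against the truth count
of covering mates) holds because the conditions make every stage
deterministic: error-free reads, 0-edit sites, one miRNA per taxon (leaf
genomes stay disjoint), GC ≥ 0.7 so every admitted window of ≥ 19 nt
passes the gate, and sites spaced at least an insert length apart.
"Covering mate" is defined generator-side as overlap ≥ site length −
max_edits, which is provably the set the fit screen admits under those
conditions.

What the studies do **not** show: performance under sequencing error
profiles (quality-dependent errors, indels), strain mixtures or plasmids,
real taxonomic structure with pervasive homology, RNAup-comparable
energies (accessibility is excluded), or the statistical behavior of sPLS
on real compositional data with depth confounding. The synthetic read
model has no quality-score information at all. Passing tests certify the
machinery — alignment, energies, LCA semantics, filters, the permutation
scheme — not field performance on real gut metagenomes.

## Numerical choices and degenerate inputs

- Alignment and duplex DP tie-breaks are deterministic (documented above),
  so identical inputs give byte-identical outputs.
- Duplex sequences are limited to 2–50 nt; non-RNA characters are errors.
- Zero-variance features: sPLS scaling raises a named error (drop the
  feature); CIM correlation rows become NA with a warning.
- clr with pseudocount ≤ 0 on zero counts is an error.
- A latent spec with no factors and zero noise is rejected as degenerate.
- The empty screen result, empty hit table and empty intersection in
  best-hit selection are all well-defined (empty list / empty table /
  union fallback or None).
- Every randomised component takes an explicit integer seed; the pipeline
  threads one global seed through sub-streams.
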