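# Methods

## Scope and model of the analysis

The pipeline reconstructs a receptor-discovery workflow over annotated
transcriptomes. It deliberately does **not** run the upstream tools
(clustering, ORF calling, BLASTP, HMMER, TMHMM, read mapping, abundance
estimation): their standard text outputs are the inputs, and the pipeline's
own contribution is (i) the domain-architecture construction and the
SR/TSR classification grammar, (ii) the TSP1 motif definitions and logo
statistics, and (iii) the expression-side selection rule with in-repo TMM
normalization.

## Annotation parsing and filtering

* Coordinates are 1-based inclusive everywhere, matching HMMER/TMHMM/BLAST
  conventions.
* Domain extent is the **envelope** (`env from`/`env to`) of the
  per-domain table, not the alignment span; envelopes are wider and are the
  conservative choice when deciding element adjacency.
* Homology filter: E ≤ 1e−10 and Metazoa taxon group. The taxonomy join is a
  plain two-column accession→group map; subjects missing from the map are
  tagged unknown and dropped with a logged count. By default only the best
  (lowest-E) hit per protein is considered — taxonomic assignment of a
  protein should reflect its closest homolog — with a `keep_all_hits`
  escape hatch.
* Proteins referenced by hit/TM files but absent from the FASTA are hard
  errors: silent mismatches between annotation layers are the classic way
  such pipelines go wrong.

## Architecture construction

* Length filter (≥ 150 aa) applies to the **protein**, not the domain
  region; sub-threshold proteins yield no architecture at all.
* Domain hits above *i*-E 1e−5 are dropped before anything else, so
  threshold changes are monotone in the element set.
* Overlap resolution is greedy: rank by (*i*-E, −bit score, start), admit a
  hit iff its overlap with every admitted hit is ≤ 25 % of the shorter one
  (`max_overlap_frac = 0.25`; at 25 % genuine adjacent domains with sloppy
  envelope edges survive while duplicate calls on the same region do not).
* TM helices are never discarded by the resolution, but a helix overlapped
  > 50 % of its length by a retained Pfam domain is suppressed in the
  arrangement string: a helix inside a domain is topology, not arrangement.
  Repeated adjacent identical domains are kept as repeats (a 14×TSP1
  hemicentin-like protein reads as fourteen TSP1 elements, because repeat
  counts are part of the family definitions).

## Classification grammar

Rules are evaluated in a fixed order (SR before TSR, specific before
generic); the first match wins, which makes the output a partition and the
precedence explicit rather than emergent. Notable choices:

* Pfam-name → concept mapping (`vocabulary.py`) is data, shipped with
  defaults (e.g. `Lectin_C` → CTLD, `TSP_1` → TSP1, `ADAM_spacer1` →
  ADAMTS-spacer) and replaceable from YAML, because the class definitions
  are about concepts, not individual Pfam families.
* SR-B's "flanked by two TMs" is implemented as: a TM entirely left of the
  CD36 envelope and one entirely right of it, with no other Pfam domain
  between each flanking TM and the loop.
* SR-E-like requires exactly one CTLD **and exactly one TM**: single-CTLD
  proteins flanked by two TMs (collectin-12-like) are classed as generic
  C-type lectins. Only "SR-E-like" is ever emitted — true SR-E status
  requires experimentally demonstrated scavenger activity, which sequence
  analysis cannot establish.
* SR-A detection rests on collagen-family + C-terminal SRCR + TM evidence
  only; no coiled-coil prediction is attempted (no reliable Pfam-level
  signal, and the class is empty in the slug data, so this path is exercised
  synthetically).
* TSP-5/COMP does not literally demand 13 type-3 repeats — profile searches
  fragment repeat regions — but ≥ 1 TSP3 plus the C-terminal lectin-like
  domain plus EGF/TSP1 evidence.
* An ADAMTS spacer without any TSP1 is still reported as ADAMTS-like, with
  the matched rule flagged "no TSP1".

## TSP1 motifs and logos

* `cysteine_count` is the raw C count of a segment; the *conserved* cysteine
  count is a property of the aligned set (C-majority columns,
  frequency > 0.5), mirroring how the domain consensus is described.
* CSVTCG and GVQTRXR are reported exact **and** with one-mismatch Hamming
  tolerance (X positions free); real repeats typically carry a motif
  *similar* to CSVTCG, and one substitution in six fixed positions is the
  narrowest useful notion of "similar". The tolerance is a parameter.
* The RXR tract accepts R/K/Q (polar residues) by default; a strict
  arginine-only mode is a flag.
* Logos: column frequency `(count + c)/(n + 20c)` with pseudocount `c`
  (default 0 — unbiased frequencies; a pseudocount matters only for
  rendering tiny sets), information `log2(20) − H` bits, no small-sample
  correction. Ambiguous residues (X) are excluded from column statistics.
  Alignment is the caller's problem: the module accepts pre-aligned input
  and only ever columnizes sets that already share one length. No MSA
  algorithm is implemented or wrapped.

## Expression analysis

* Low-count filter: ≥ 100 raw counts in ≥ 2 samples, applied before
  normalization.
* TMM follows the canonical definition exactly (double trim 30 % on M,
  5 % on A, inverse asymptotic-variance weights, reference = sample with
  upper-quartile fraction closest to the mean, geometric-mean-1 rescale);
  the test suite pins it to Bioconductor edgeR's `calcNormFactors` at
  rtol 1e−6 and to an independent direct-summation oracle.
* `L2FC = log2((meanCPM_a + 0.5)/(meanCPM_b + 0.5))`; the 0.5 CPM prior
  only guards zeros and is configurable. For triplicated groups, CPMs are
  averaged after normalization.
* Significance **is** the threshold rule |L2FC| > 1 — no dispersion
  estimation, no p-values, no multiple-testing correction. Two of the three
  designs have single libraries per condition, where model-based inference
  has nothing to estimate; the threshold rule is then also applied uniformly
  to the triplicated design for comparability. Selection: fed-vs-starvation
  designs require L2FC > 1 in *every* comparison; the staged juvenile
  design selects the initial-phase upregulated set (per-stage up/down calls
  are also exported).

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (plan, seed) and write the exact dialects
the parsers read, so every stage has a round-trip contract and planted
truth.

* **Proteomes**: each category has a template realizing its defining
  arrangement; real hits get *i*-E in 10⁻³⁰–10⁻⁶, distractor hits land just
  above the 1e−5 threshold (Poisson rate 0.3/protein by default) so correct
  threshold handling is observable. Amino-acid content is uniform — the
  pipeline never re-detects domains from sequence, so only coordinates and
  labels need to be faithful. Not emulated: fragmented ORFs, chimeric
  transcripts, split domain envelopes, biased composition. Passing tests
  therefore demonstrate rule correctness, not robustness to assembly
  artifacts.
* **TSP1 sets**: 56-column segments with motifs planted at fixed columns and
  a cysteine-free background, giving exactly six cysteines per segment and
  unambiguous conserved columns. Real repeats vary in length and require
  alignment, which is out of scope here.
* **Counts**: negative binomial with `var = μ + φμ²`, φ = 0.1 (a typical
  bulk RNA-seq biological dispersion), log-normal baselines
  (log2 mean 7, sd 1.5), ~1 M reads/library, 1,000 genes, 20 planted
  candidates at log2 effect 2 — scaled-down but structurally faithful study
  designs (one library per condition for the adult series; triplicates of
  apo/fed5/fed7/fed10 for the juvenile series, planted genes elevated from
  fed5 onward so the initial contrast carries the effect). Problem sizes
  were chosen so the whole suite runs in seconds while leaving the
  recovery statistics stable. Not emulated: GC/length biases, batch
  effects, mapping ambiguity.

At these conditions the all-comparisons rule on the **unreplicated** design
has per-gene power ≈ 0.91 at log2 effect 2 (M-value sd ≈ 0.65), so the
≥ 0.95-sensitivity recovery property is demonstrated on the triplicated
design (power ≈ 0.99) and the unreplicated design is exercised at planted
effect 3, where recovery of ≥ 19/20 planted genes is expected.

## Numerical details and degenerate inputs

* Overlap-resolution ties: (lower *i*-E, higher bit score, lower start);
  empty input → empty output.
* TMM degenerate cases: identical columns give factor exactly 1 (the
  |M| < 1e−6 early exit); an all-zero sample is a hard error; genes zero in
  either compared sample are excluded pairwise.
* Logo columns consisting only of X are a hard error; information is clipped
  to [0, log2 20] against floating-point drift.
* All randomness flows through `numpy.random.default_rng(seed)`; derived
  seeds stay below 2³¹.

## Known limitations

* Classification is only as good as the Pfam vocabulary mapping; unmapped
  families never match and bias toward `unclassified`/`TSR_other`.
* The threshold-only significance rule has no error control; on ~1,000 null
  genes in the unreplicated design, ≈ 1 % pass both contrasts by chance.
* The logo module does not align; heterogeneous-length TSP1 segments must be
  aligned upstream.
* Real TMHMM/HMMER edge cases (broken lines, partial files) are rejected,
  not repaired.
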