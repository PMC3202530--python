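# Methods and design notes

## Coordinate model

Every interval in the package is 1-based and inclusive at both ends,
matching the DAS 1.53 segment addressing scheme (`chrom:start,end`).
Length is `end − start + 1`; two intervals on the same chromosome
intersect iff `max(starts) ≤ min(ends)`, so touching endpoints overlap.
Chromosome names are stored without a `chr` prefix; parsers strip one
case-insensitively, since DAS segment ids and DTC raw files both omit
it. BED-style 0-based half-open input, if ever encountered, must be
converted at the I/O boundary — nothing downstream re-interprets
coordinates. Strand is carried through parsing and serialization but
ignored by layout and rendering; the three views are strand-agnostic.

## DAS I/O

The reader is lenient and the writer strict. Parsing accepts any
document whose element skeleton is `SEGMENT/FEATURE` with `TYPE`,
`METHOD`, `START`, `END` and optional `SCORE`, `ORIENTATION`, `NOTE`,
`LINK` children; unknown attributes and child elements are ignored, so
replies from servers of slightly different protocol vintages still
parse. A record violating the feature invariants (e.g. `START > END`)
is dropped with a logged warning and the rest of the document parses.
Malformed XML raises a parse error carrying the line number reported by
`lxml`.

The writer emits a fixed attribute order, two-space indentation, `\n`
line endings and UTF-8, so output is byte-stable across runs — this is
what makes fixture determinism and round-trip testing exact. Scores
serialize via `repr` (integral values without the trailing `.0`), which
`float()` inverts losslessly for finite values.

Retrieval issues one request per (source, window) with no tiling. A
single request is capped at 50 Mb of sequence by default; a renderer
designed for a few thousand features per screen has no use for
whole-genome pulls of dense sources, and the cap fails fast instead of
exhausting memory. HTTP sources (stdlib `urllib`) use a 10 s timeout
with 2 retries and an optional per-session response cache keyed by
(URL, segment), since slow links dominate interactive latency. A
"file mode" source — a directory of canned replies named
`features.segment={chrom}_{start}_{stop}.xml` plus a `manifest.tsv` —
is this package's own convention so every test and offline session runs
without a server. A failing source raises an error carrying its URL and
never affects other tracks in the session.

## Personal genotypes and trio logic

The raw dialect is tab-separated `rsid, chromosome, position, genotype`
with `#` comments. Calls are 1–2 characters over `{A,C,G,T,D,I,-}`:
`--` is an assayed no-call, a single letter is hemizygous, and `D`/`I`
(deletion/insertion alleles) pass through all logic as opaque symbols —
trio splitting is allele-agnostic. Malformed rows are dropped with
warnings; on duplicate rsids the last row wins, matching
last-write-wins file regeneration. A site absent from a chip is "not
assayed", which is deliberately distinct from `--`: chip density counts
no-calls (they reflect chip content) but not absent sites.

A profile converts to DAS features with `start = end = position` and
the genotype string as the DAS type id, so a generic DAS popup displays
the call with no genotype-specific client code.

Trio consistency enumerates the four ordered parental transmissions
(one allele from each parent's pair) and keeps those whose unordered
pair equals the child's; the verdict is consistent iff at least one
survives, and all survivors are reported. No-call or hemizygous
participants make the verdict undecidable rather than guessed.
Inconsistencies are reported, never repaired — de novo mutation
handling is out of scope. Extended relatives (siblings, aunts) appear
in the genotype table but do not constrain the verdict; no pedigree
likelihood model is attempted.

## Query grammar and resolution

Routing is purely syntactic and total: `chrom:start,end` (optional
`chr` prefix; the Unicode ratio colon U+2236 is accepted because word
processors substitute it for `:`) is a region, a bare `rs`-number is a
SNP, anything else is a gene symbol. An rsID absent from all loaded
sources is an error, never a silent fallback to gene search —
predictability beats cleverness in a query box. SNP hits open a window
of ±100 kb (configurable, `snp_window_half`) clamped to the chromosome;
when sources disagree on an rsID's position the first-loaded source
wins with a warning. Gene lookup is a case-insensitive exact label
match; duplicates raise an ambiguity error listing candidates, and
prefix suggestions are sorted and capped at 20. Ensembl links default
to the May-2009 archive host, the era matching NCBI36 coordinates, and
are configurable.

## Rendering

The three views share an affine base→pixel map (`window.start → 0`,
`window.end → width`); its inverse recovers a position to within one
base at any practical zoom. The `track` device packs features by greedy
first-fit into rows — sorted by (start, end, id), each feature lands in
the lowest row it clears by `min_gap_px` — which conserves the feature
count and provably never overlaps within a row. `mark` draws midpoint
glyphs, `line` draws all boxes on one row (overlaps allowed), and
`chart` draws a 100-bin count histogram scaled to the lane height; the
latter two semantics are this package's choices where the device names
alone underdetermine behavior, and both bin count and lane geometry are
parameters.

Features partially inside the window are clipped for drawing but still
count toward the legend: intersection with the window is what "in this
region" means under segment semantics. Legend text is exactly
`{display name} ({count})`. Ideogram stains map gneg→white,
gpos25/50/75/100→25/50/75/100 % gray, acen→red, gvar→light gray,
stalk→hatched. Interactivity is headless: chromosomes carry ids
`chr-{name}`, bands `band-{chrom}-{band}`, features
`feat-{track}-{id}` with popup metadata (`data-*` attributes), so
behavior can be attached by a wrapper. SVG is assembled by a small
deterministic builder with fixed attribute order and 2-decimal
coordinates; identical inputs yield byte-identical documents.

## Synthetic fixtures: what they emulate and what they don't

The generator reproduces the *structure* of a DTC analysis session,
not real database content. The family case fixes the scenario's
landmarks — rs10993994 at 10:51,219,502 with calls TT (son), CT
(mother, father, sister), CC (aunt); MSMB starting 57 bp after the SNP;
four somatic mutations inside MSMB; four CNVs overlapping the ±100 kb
window — and fills the window with evenly spaced filler SNPs such that
the son's chip assays 6 sites and the newer chip of the other members
12, a strict superset, emulating a chip-version upgrade that doubled
feature density. The absolute counts 6 and 12 are the smallest round
numbers realising the 2× ratio; only the ratio is meaningful. MSMB's
end (51,232,000) and all filler/neighbour-gene intervals are invented.

The region case encodes the 15q11 result shape: 45 genes inside
15:20,000,000–24,000,000 (plus three outside the window to exercise
intersection filtering), 15 of them disease genes including UBE3A, and
a 400,000 bp deletion labelled "Variation 7051" overlapping UBE3A. Gene
positions other than UBE3A's are drawn from a seeded RNG.

Chromosome lengths are the real NCBI36 values, so entry-point documents
and window clamping behave as on live data. Cytobands are synthetic:
eight bands per chromosome (three per arm plus an acen pair), with the
centromere at 45 % of length — except chromosome 15, placed at 17 %
to reflect its acrocentric shape so that the band containing
20–24 Mb is named q11 as in the real karyotype. Real banding would
require a download and adds nothing to the logic under test.

Consequently, passing tests demonstrate correct parsing, filtering,
counting, inheritance logic and layout — they say nothing about the
content fidelity of any live annotation database, about real chip
manifests (~600 k SNPs; fixtures are window-scale), or about cross-source
coordinate discrepancies beyond what the fixtures encode.

## Numerical and scale choices

Randomized stress sources place features uniformly with log-uniform
lengths in [1, 10⁶] bases, spanning point SNPs to megabase CNVs. The
stress render uses 5,000 features — the scale at which a browser screen
remains legible and which the renderer is designed to handle in one
pass — over a 50 Mb window; the acceptance script and tests finish it
in seconds. All generators take explicit seeds and are byte-reproducible.
Pixel coordinates are emitted at 2-decimal precision; the inverse map's
guarantee is ±1 base, which is exact at any zoom where one pixel covers
at least one base.

## Known limitations

No DAS writeback, stylesheet support or registry discovery; no
liftover between assemblies (one assembly per session); no fuzzy or
alias-based gene matching; no phasing beyond single-site trio splits
and no pedigree use of non-trio relatives; vendor risk-score
arithmetic is out of scope (risk figures in vendor reports are quoted
values, not recomputed); identifier lookup (rsID/gene) requires local
file-mode sources, since a remote DAS server cannot be enumerated
without a segment.
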