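# karyodas

A headless client for the Distributed Annotation System (DAS), built for
exploring direct-to-consumer (DTC) genotype data in its genomic context.
It fetches and parses DAS 1.53 XML feature sources, answers region /
gene / SNP queries, renders three synchronized views — karyotype,
chromosome and zoom — as SVG, and analyses family genotype profiles
(Mendelian trio consistency, SNP chip density) against reference
annotation tracks such as gene, disease-gene, somatic-mutation and
copy-number-variation sources.

It is aimed at bioinformaticians who want scriptable, offline-testable
genome-browser plumbing: every interactive concept (clickable
chromosomes and bands, feature popups, track legends with feature
counts) is represented as stable element ids and embedded metadata in
the SVG, so a thin web wrapper can add behavior without the core
knowing about it.

## The model in brief

* **Coordinates** are 1-based, fully inclusive on both ends (the DAS
  segment convention); a region `chrom:start,end` has
  `end − start + 1` bases, and two regions intersect iff
  `max(starts) ≤ min(ends)` on the same chromosome.
* **Genotypes as annotations.** A personal genotype file (tab-separated
  `rsid  chromosome  position  genotype`) becomes a DAS source whose
  per-SNP features carry the genotype call in the DAS *Type Id* field,
  so any DAS client shows the call in the feature popup.
* **Mendelian trio consistency** at one site: a child's diploid call
  {c₁,c₂} is consistent iff it can be split with one allele from the
  mother's pair and one from the father's; all compatible
  (maternal, paternal) transmissions are enumerated.
* **Track layout** uses greedy first-fit interval packing: features
  sorted by (start, end, id) each drop into the lowest row their pixel
  interval fits, so overlapping annotations stack without collisions.
* Legends read `display name (count)` where the count is the number of
  the track's features intersecting the current window; features
  straddling a window edge are clipped for drawing but still counted.

The default assembly is human NCBI36 (hg18), the coordinate basis of
the classic 23andMe raw download; the assembly is configurable.

## Worked example

Generate the synthetic family fixture (five genotype sources plus gene,
cancer-mutation and variable-region tracks on chromosome 10) and ask
how the prostate-cancer risk genotype at rs10993994 was inherited:

```sh
karyodas fixtures make family-case --outdir fam
karyodas query rs10993994 --fixture-dir fam
karyodas family --snp rs10993994 \
    --child fam/raw/son.txt --mother fam/raw/mother.txt \
    --father fam/raw/father.txt \
    --other fam/raw/sister.txt --other fam/raw/aunt.txt
```

The query prints the zoom window centred ±100 kb on the SNP:

```
chrom	10
start	51119502
end	51319502
ensembl	http://may2009.archive.ensembl.org/Homo_sapiens/Location/View?r=10:51119502-51319502
```

and the family command prints the per-member calls and the trio
verdict:

```
son	TT
mother	CT
father	CT
sister	CT
aunt	CC
consistent	yes
transmissions	maternal T/paternal T
```

Both parents are CT heterozygotes; the only transmission compatible
with the son's TT is a T from each parent — the homozygous risk
genotype arose by ordinary Mendelian inheritance, not a de novo event.
Rendering the window shows the density difference between chip
versions (the son's older chip assays 6 SNPs here, every other
relative's newer chip 12) and the annotation context — the MSMB gene
starts 57 bp after the SNP:

```sh
karyodas render --view zoom --region 10:51119502,51319502 \
    --fixture-dir fam --outdir out
# legend lines printed include:  cancer mutations (4)
```

The second bundled scenario is a region search over the 15q11 deletion
region (`karyodas fixtures make region-case --outdir reg`, then
`karyodas query "15:20000000,24000000"`): 45 genes in the window, 15 of
them disease genes, with UBE3A overlapped by a 0.4 Mb deletion CNV
("Variation 7051").

## Layout

```
src/karyodas/core.py       domain types + interval algebra
src/karyodas/das.py        DAS 1.53 XML read/write/fetch, raw export
src/karyodas/fixtures.py   deterministic synthetic data generator
src/karyodas/personal.py   DTC genotype parsing + trio analysis
src/karyodas/query.py      query grammar, SNP/gene resolution, config
src/karyodas/render.py     packing, pixel maps, SVG views
src/karyodas/cli.py        command-line entry point (karyodas ...)
docs/methods.md            models, parameters, design notes
```
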