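# kdrseq

Amplicon-based surveillance of knockdown-resistance (**kdr**) mutations in
the voltage-gated sodium channel gene (*vgsc*) of *Aedes aegypti*.

Pyrethroid insecticides target the mosquito voltage-gated sodium channel;
point mutations in segment 6 of domains II and III (DII-S6, DIII-S6) —
S989P, V1016G, T1520I, F1534C/L and friends — reduce pyrethroid binding and
confer knockdown resistance. Surveillance programs genotype these sites by
PCR-amplifying the two regions from individual mosquitoes, Sanger-sequencing
2–3 plasmid clones per amplicon, and comparing the translated sequences to a
reference gene model. `kdrseq` turns that desk procedure into a reproducible
pipeline for anyone running or re-analysing such surveys:

1. **In-silico PCR** — locate the primer pair on either strand of each clone
   read (ungapped, IUPAC-aware, configurable mismatch tolerance), orient and
   trim the amplicon.
2. **Clone consensus** — strict per-position majority across the clones of
   one mosquito; ties become IUPAC ambiguity codes and are flagged
   discordant.
3. **Alignment** — deterministic affine-gap semi-global alignment of each
   consensus onto its reference region (match +2, mismatch −3, gap open −5,
   gap extend −2; identity floor 0.8 guards against off-target products).
4. **Codon calling** — project the alignment onto the exon-aware codon map,
   translate every fully covered in-frame codon, and classify each
   amino-acid substitution against a kdr-site catalogue
   (`validated_kdr` / `watch` / `other` / `ambiguous`).
5. **Haplotyping** — combine the calls at positions 989/1016/1520/1534 into
   a labelled combination haplotype (the recurrent combinations carry the
   fixed survey labels H1–H11; novel tuples get stable `N{k}:` labels).
6. **Reporting** — paired-amplicon sample filter (individuals lacking either
   region are excluded), then per-population carrier-frequency tables with
   half-up one-decimal percentages.

A synthetic-cohort generator (`kdrseq.cohort`) produces clone-level FASTA
files, a manifest and a ground-truth table from a declarative cohort
specification — planted haplotypes at chosen per-population counts,
clone-level substitution noise, amplification dropout, random flanks and
strands — so the whole pipeline is testable end to end without any
downloads. A bundled *synthetic* vgsc gene model (`kdrseq.bundled`) carries
the published primer pairs, the wild-type residues at all surveyed sites and
an intron inside the DIII-S6 amplicon; users with the real reference supply
it at runtime via `load_gene_model`.

## Worked example

Reproduce a five-township Mandalay-area survey (394 mosquitoes with both
amplicons recovered) whose carrier counts are encoded in
`kdrseq.datasets.mandalay_survey_spec`:

```python
from kdrseq.datasets import mandalay_survey_spec
from kdrseq.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(simulate=mandalay_survey_spec(seed=1)))
print(result.mutation_table.formatted().to_string())
```

```
         Naung Cho Chan Aye Thazan  Patheingyi Aung Myae Tharsan Pyin Oo Lwin        Total
S989P   54 (38.8%)      67 (51.5%)  66 (79.5%)        21 (70.0%)    8 (66.7%)  216 (54.8%)
V1016G  97 (69.8%)      90 (69.2%)  73 (88.0%)        21 (70.0%)    9 (75.0%)  290 (73.6%)
F1020S  22 (15.8%)      20 (15.4%)    4 (4.8%)          2 (6.7%)    2 (16.7%)   50 (12.7%)
T1520I    1 (0.7%)        1 (0.8%)    0 (0.0%)          0 (0.0%)     0 (0.0%)     2 (0.5%)
F1534C  75 (54.0%)      88 (67.7%)  74 (89.2%)        26 (86.7%)   11 (91.7%)  274 (69.5%)
F1534L    0 (0.0%)        0 (0.0%)    2 (2.4%)          0 (0.0%)     0 (0.0%)     2 (0.5%)
E1553G    0 (0.0%)        9 (6.9%)    0 (0.0%)          1 (3.3%)     0 (0.0%)    10 (2.5%)
```

Each cell is `carriers (percentage of the column's retained individuals)`:
290 of 394 mosquitoes (73.6%) carry V1016G, the two F1534L carriers sit in
the 83-mosquito Patheingyi sample (2.4%), and so on. The planted counts come
back out exactly because the simulated reads are noise-free and the pipeline
recovers every planted codon edit; with `noise_rate > 0` the clone-majority
consensus absorbs almost all simulated Sanger errors.

The same run exposes `result.haplotype_table` (H1–H11 combination
haplotypes per township), `result.shares` (cohort composition:
139/130/83/30/12 mosquitoes → 35.3/33.0/21.1/7.6/3.0%), the per-individual
calls and haplotypes as DataFrames, and — via `out_dir` — TSV/JSON/VCF
files for all of the above.

The same stages are scriptable from the shell:

```sh
kdrseq simulate --survey --seed 1 --out-dir sim/
kdrseq call --fasta DII-S6=sim/DII-S6.fasta --fasta DIII-S6=sim/DIII-S6.fasta \
            --manifest sim/manifest.tsv --out-dir out/
kdrseq run --config pipeline.json --seed 1       # all stages from one JSON
```

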