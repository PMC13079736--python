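# retronscan

Design of barcoded retron donor oligo pools for phage-carried
sensor-effector transgenes, and the short-/long-read sequencing pipelines
that quantify, track, and classify variant enrichment across directed
evolution cycles.

## The problem

Retron recombineering turns an *E. coli* host into an in vivo mutagenesis
machine: a plasmid-encoded retron produces a single-stranded DNA donor that
installs a programmed edit into a replicating M13 phage genome. Pooled,
barcoded donor libraries make this a targeted diversification strategy for
phage-assisted evolution — deep mutational scanning (DMS) of an inserted
sensor domain, or insertion/deletion scanning of the sensor-effector
junction linkers of an allosteric switch (an AraC-LOV-type fusion, in the
motivating application). Each donor encodes a 90 nt homology region with
the edit centered in the synthesized oligo:

    fwd_barcode | TypeIIS flank | 90-nt donor (edit centered) | TypeIIS flank | rev_barcode

Selection outcomes are read out by sequencing: paired-end short reads for
per-position substitution frequencies and edited/wild-type classification,
and full-length long reads for in-frame indel calling at the junctions,
temporal enrichment across selection steps, and within-read mutation
co-occurrence.

`retronscan` implements all of this as a library plus a CLI, together with
a seeded synthetic-data module (pools, selection trajectories, reads with
realistic error structure) so that every stage is testable end to end
without external data.

## Core definitions

* An edit replaces reference interval `[nt_start, nt_end)` with `payload`;
  all designed edits are in-frame (net change divisible by 3, |net| <= 15 nt).
* Donor = 90 nt of the *edited* sequence, payload centered; with payload
  length `p`, left arm = floor((90−p)/2), right arm = ceil((90−p)/2).
* DMS library = every codon of the target region x all 20 residues, each
  encoded by the host's most preferred codon; |library| = codons x 20.
* Per-position mutation rate = non-reference count / depth, at nucleotide,
  codon, and amino-acid level; positions under 2,000 reads are masked.
* Long-read QC: 1800 < length < 2200 (strict) and mean quality Q > 20,
  with mean Q = −10·log10(mean per-base error probability).
* Temporal enrichment: corrected(r, s) = raw(r, s) − raw(r, baseline),
  baseline = the first mutagenesis passage.

## Worked example

Design the scanning library for the packaged fixture construct (a
synthetic 1998-nt sensor-effector transgene with a 141-codon insert behind
SG/GS junction linkers):

```sh
$ retronscan design-dms --fixture --out demo/dms
$ python -c "import json; print(json.load(open('demo/dms/manifest.json'))['results'])"
{'n_designed': 2820, 'n_noop': 52, 'outputs': ['dms_pool.fasta', 'dms_manifest.tsv']}
```

2820 = 141 insert positions x 20 residues; 52 entries are wild-type
recodings whose preferred codon already matches the native codon (kept,
flagged no-op). The manifest names each variant in the insert's published
residue numbering (`Q404A`, ...) alongside its construct coordinates.

Simulate a dual-barcoded paired-end run from a pool in which ten codon
substitutions share 40% of the mass over a 60% wild-type background, then
run the scanning pipeline on it:

```sh
$ retronscan simulate --fixture --n 2000 --seed 11 --background-freq 0.6 --out demo/sim
$ retronscan run-illumina --fixture \
    --r1 demo/sim/reads_R1.fastq --r2 demo/sim/reads_R2.fastq \
    --scheme demo/sim/barcodes.tsv --mode dms --min-depth 100 --out demo/run
```

The run manifest reports `demux_assigned: 1000, demux_rejected: 0` (1000
pairs, exact dual-barcode matching) and the per-position table
`SP1_positions.tsv` recovers the programmed variants:

```
 position ref  depth  count_A  count_C  count_G  count_T  mutation_rate  masked
      120   A   1000        0        0       41        0          0.041   False
      122   T   1000        0        0       41        0          0.041   False
      123   G   1000        0        0        0       31          0.031   False
```

The simulator's ground truth (`demo/sim/manifest.json`) drew variant
`T41A` on 41 of 1000 template molecules — the pipeline reports exactly
41/1000 = 0.041 at that variant's codon (positions 120-122), since the
reads are error-free at the default settings. With `--sub-rate` above
zero, recovery is exact up to binomial sampling plus the error rate.

The same library API is available in Python:

```python
from retronscan import make_fixture_construct, design_dms, design_linker_library

construct = make_fixture_construct()
dms = design_dms(construct, "insert_domain")        # 2820 donors
linkers = design_linker_library(construct)          # 113 junction variants
max(abs(d.edit.net_delta) for d in linkers)         # 15 (nt)
```

## Layout

| module | contents |
| --- | --- |
| `reference_model` | annotated transgene construct, junction motif anchoring, packaged fixture |
| `library_design` | edits, 90-nt donors, DMS + linker libraries, barcoding, pool export |
| `synthetic_data` | variant pools, fitness/bottleneck selection, Illumina/long-read simulators |
| `illumina_pipeline` | demux, trimming, local alignment, DMS/linker counting, pair classification |
| `longread_pipeline` | QC, indel correction, junction calling, enrichment, co-occurrence, logos |
| `cli` | `retronscan` subcommands wrapping the above, with JSON run manifests |
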