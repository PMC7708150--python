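# varsense

Library-size planning and sensitivity benchmarking for somatic variant
calling in cancer RNA-Seq.

## The problem

RNA-Seq can recover transcribed somatic mutations alongside expression, but
coverage at a variant site depends on how highly the host gene is expressed
and on the total library size. When designing a sequencing study the key
question is: *how many fragments must be sequenced to reliably detect
mutations in the genes of interest?* `varsense` answers it two ways:

1. **Planning.** The expected total read depth at a variant site in a gene
   expressed at a given RPKM connects depth, read length and library size:

   ```
   library_size = (mean depth at variant site × 1e3 × 1e6)
                  / (gene RPKM × read length × 2)
   ```

   (the 2 is the two reads per paired-end fragment). A 30X target in a
   4-RPKM gene with 100 bp PE reads needs 37.5M fragments; a 20X target
   needs 25M.

2. **Staged-sequencing simulation.** Deeply sequenced call sets are
   binomially thinned to a ladder of smaller library sizes (replicated with
   fixed seeds), two filtering strategies are applied — *default-filters*
   (caller PASS flag + panel-of-normals removal) and *annotation-filters*
   (COSMIC/dbSNP/ExAC knowledge, exon-boundary/homopolymer/repeat context,
   and hard quality thresholds: base quality > 18, alt depth ≥ 5, total
   depth ≥ 15, VAF ≥ 0.03) — calls are matched against a validated truth
   set (exact for SNVs; a ±50 bp window with optional ≥3 bp partial allele
   overlap for indels), and recall `TP/(TP+FN)` is reported overall, per
   total-depth stratum and as a function of a depth threshold *d*.

A synthetic-cohort generator provides every input with known ground truth:
an AML-like 88-variant truth set with published VAF ranges, a 17-normal
panel with planted recurrent artifacts and a low-VAF COSMIC hotspot (the
NRAS scenario), expression-driven site depths, annotation resources with
single-reason decoys, and emulated caller profiles (block vs split indel
representation, clustered-events flagging).

## Worked example

```python
from varsense import required_library_size, run_benchmark, BenchmarkConfig
from varsense.sensitivity import aggregate_replicates

plan = required_library_size(target_depth=30, rpkm=4, read_length=100)
print(f"required library size: {plan.required_fragments_millions:.1f}M fragments")

result = run_benchmark(BenchmarkConfig(seed=100))
summary = aggregate_replicates(result.sensitivity)
snv = summary[(summary.truth_set_id == "SNV")
              & (summary.strategy == "annotation")
              & (summary.caller_id == "vardict_like")]
print(snv[["library_size", "median", "min", "max"]].to_string(index=False))
```

prints

```
required library size: 37.5M fragments
 library_size  median    min    max
   20000000.0  0.9655 0.9655 0.9828
   30000000.0  0.9828 0.9828 1.0000
   40000000.0  0.9828 0.9828 1.0000
   50000000.0  1.0000 1.0000 1.0000
   80000000.0  1.0000 1.0000 1.0000
  113000000.0  1.0000 1.0000 1.0000
```

The first line is the planning formula; the table is the median (with min
and max across replicate downsampling runs) SNV recall of one emulated
caller under annotation-filters: recall is complete down to 50M fragments
and degrades as the library shrinks, with the largest loss at 20M — the
qualitative behaviour the simulation is built to expose. The same result
object carries the indel recall, the per-depth-interval strata, the
cumulative recall at each depth threshold and the removal-reason counters.

The same machinery is scriptable from the shell:

```sh
varsense plan --depth 30 --rpkm 4 --read-length 100
varsense simulate --seed 100 --out-dir cohort/
varsense run --seed 100 --sizes 80M,50M,40M,30M,20M --out-dir bench/
```

See `docs/methods.md` for the model and its assumptions.

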