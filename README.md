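# ampliref

A curation toolkit for body-site-focused 16S rRNA reference databases.

16S rRNA gene surveys of human body sites routinely stop at genus-level
resolution, which blurs the distinction between harmless commensals and
pathogens of the same genus (*Staphylococcus aureus* vs
*S. epidermidis*, *Corynebacterium propinquum* vs *C. accolens*).
Species-level resolution is achievable with a small, highly curated
reference set in which each species-level taxon holds a stable **HMT
(human microbial taxon) number** and one to six manually curated
reference sequences. `ampliref` implements the machinery for building
and evaluating such databases:

* **Assignment** — blastn-style best-hit classification: a query is
  assigned to a species when its best reference hit reaches ≥98.5%
  identity over ≥98% query coverage; best hits in the [98, 98.5)% band
  are set aside as ambiguous. Includes threshold sweeps and
  database-vs-database disagreement reports.
* **Expansion** — grow the database from clone libraries: cluster
  unassigned clones into M-OTUs (greedy centroid clustering, ≥98.5%
  identity over ≥99% coverage), promote clusters with ≥10 members to
  provisionally named candidate taxa (`Genus bacterium HMT-xxx`,
  `Family [G-n] bacterium HMT-xxx`), and re-classify.
* **Region resolution** — extract V1-V3 / V3-V4 / custom amplicon
  regions by IUPAC-aware primer matching, count taxa that become
  indistinguishable at identity thresholds (single-linkage collapse),
  and emit naive-Bayes training sets in which indistinguishable
  same-genus taxa are merged into **supraspecies**
  (`Staphylococcus capitis_caprae`) to preserve subgenus resolution.
* **Habitat preference** — a deterministic screen over taxon × body-site
  count tables: normalise each site to 20,000 clones, compute each
  taxon's focal-site enrichment ratio against an even spread across all
  sites, and call a taxon focal-site-preferred if it ranks in the top 20
  and is enriched ≥2×.
* **Synthetic data** — seeded generators of 16S-like references, clone
  libraries and count tables with planted ground truth (region-identical
  taxon pairs, novel lineages, enrichment factors), so the whole
  pipeline is testable without downloads.

The core quantities, for query *q* against reference *r* under local
alignment: identity = matches / aligned columns (internal gaps
included), coverage = query span / |q|; assignment requires
identity ≥ 98.5 ∧ coverage ≥ 98. Habitat ratio for taxon *t* at focal
site *s*: r(t) = p_s(t) / (100 / n_sites), where p_s(t) is the percent
of *t*'s site-normalised clones found at *s*.

## Worked example

Simulate a small database and clone library, then classify:

```bash
cat > sim.json <<'EOF'
{"n_taxa": 6, "n_reads": 30, "error_rate": 0.002,
 "planted_novel": [[12, 5.0]]}
EOF
ampliref simulate refs   --config sim.json --seed 3 --out sim/
ampliref simulate clones --config sim.json --seed 3 --out sim/
ampliref classify --db sim/refs.fa --tax sim/refs.tsv \
    --queries sim/clones.fa --out cls/
```

prints

```
30/42 identified (71.4%)
```

— the 30 background reads hit their source taxa above threshold, while
the 12 reads of the planted novel lineage (5% diverged from every
reference) stay unassigned. One expansion round recovers it:

```bash
ampliref expand --db sim/refs.fa --tax sim/refs.tsv \
    --queries sim/clones.fa --out expanded/
```

```
added 1 taxa; 71.4% -> 100.0% identified
```

`expanded/report.json` shows the new taxon (HMT-106, 12-member M-OTU,
nearest reference ≈93% identity) and `expanded/refs.tsv` now carries its
provisional name. Region resolvability and the training set:

```bash
ampliref resolve  --db sim/refs.fa --tax sim/refs.tsv --region V1-V3 \
    --thresholds 99,99.5,100 --out res/
ampliref trainset --db sim/refs.fa --tax sim/refs.tsv --out train/
```

Every command writes a `manifest.json` (config, input digests, version,
seed) so runs are reproducible.

## Layout

```
src/ampliref/
  alignment.py   # exact local + end-gap-free DP engines (numba)
  refdb.py       # HMT data model, FASTA/TSV I/O, allocation, naming
  assign.py      # best-hit classification, sweeps, db comparison
  regions.py     # primer matching, region extraction, collapse, trainsets
  expand.py      # M-OTU clustering, min-support rule, expansion rounds
  habitat.py     # body-site preference screen
  synthetic.py   # seeded generators with planted truth
  cli.py         # `ampliref` entry point
docs/methods.md  # models, defaults, conventions, limitations
```
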