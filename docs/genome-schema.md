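# The geval-json genome format

A genome is a single JSON object. All coordinates are 1-based inclusive.

```json
{
 "genome_id": "511145.12",
 "name": "Escherichia coli str. K-12 substr. MG1655",
 "domain": "bacteria",
 "lineage": ["Enterobacteriaceae", "Escherichia", "Escherichia coli"],
 "contigs": [
  {"contig_id": "c1", "length": 4641652}
 ],
 "features": [
  {
   "feature_id": "fig|511145.12.peg.1",
   "contig_id": "c1",
   "start": 190,
   "end": 255,
   "strand": "+",
   "function": "Thr operon leader peptide",
   "protein_length": 21
  }
 ]
}
```

Field notes:

* `domain` — `"bacteria"` or `"archaea"`.
* `lineage` — non-empty, ordered most general to most specific. Marker-set
  selection walks it from the specific end; by default the last three
  entries are read as family, genus, species.
* `contigs[].length` — positive; every feature must lie within its contig.
* `features[].function` — free-text SEED/RAST-style function. Multi-role
  functions separate roles with `" / "`, `" @ "` or `"; "`; a trailing
  `" # ..."` is a curator comment and is ignored.
* `features[].protein_length` — optional, amino-acid residues; used only
  for the good-seed (pheS length) classification.

## GFF3 import

`parse_genome(path, format="gff3+functions-tsv", functions_path=..., lineage=...)`
reads CDS features from a GFF3 file (contig lengths from the
`##sequence-region` directives) and takes functions from a side TSV with
columns: feature id, function, optional protein length. The side channel
exists because free-text functions do not survive GFF3 attribute escaping
reliably.
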