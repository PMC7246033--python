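# panel218.tsv changelog

The panel fixture transcribes the published 218-antibody / 20-category table
(218 primary entries, 73 parenthetical overlap references). The printed
per-category overlap counts sum exactly to 73, but several itemized
parenthetical lists are internally inconsistent with their own printed counts.
Every departure from a literal transcription is recorded here; nothing was
corrected silently.

## Spelling normalization (overlap references must resolve by exact name)

- `ERK1` / `p-ERK` (NFkB overlaps) → `ERK-1` / `p-ERK-1` (the RAS primary spellings).
- `NRF2` (survival/protection overlaps) → `NRF-2` (the NFkB primary spelling).
- `CD31` and `PECAM (CD31)` → `PECAM-1 (CD31)` (the downregulated-inflammatory
  primary spelling).
- `VCAM (CD106)` → `VCAM-1 (CD106)`.
- `MMP-3, -9, -12` expanded to `MMP-3`, `MMP-9`, `MMP-12`.
- `S-100. integrin α5` read as two entries (`S-100`, `integrin α5`); the period
  is a typo for a comma.

## Count reconciliations

- **Differentiation-related primaries**: the printed count is 11 but only 10
  names are itemized. `AP1M1` is promoted to the 11th primary: it appears in
  the differentiation parenthetical (where it cannot resolve, having no primary
  row anywhere) and carries a measured differentiation result (+12.8%) in the
  source, so the most economical reading is that it was dropped from the
  primary list by a typesetting error. Tagged `reconstructed`.
- **Protection-related overlaps**: printed count 13, but the itemized list
  repeats `PLC-β2` and `PI3K` and includes `PLC-β2`, which has no primary row
  in any category (although it, too, carries measured values in the source).
  The 10 distinct resolvable names are kept; the remaining 3 slots are filled
  with `p38`, `p-p38`, `PTEN` (stress-response/survival proteins, primaries in
  NFkB/RAS, attested in the source's protection–survival discussion). Tagged
  `reconstructed`.
- **Differentiation-related overlaps**: 12 itemized vs. printed count 11;
  after removing the unresolvable `PLC-β2` and promoting `AP1M1` (above), the
  11th slot is filled with `TGase 2`, which the source's differentiation
  results measure (+17.6%) and which is a protection primary. Tagged
  `reconstructed`.
- **Angiogenesis-related overlaps**: the itemized list contains both `CD31`
  and `PECAM-1 (CD31)` (the same antibody), leaving 8 distinct names for a
  printed count of 9. The 9th slot is filled with `CTGF` (growth-factor
  primary; its decrease is discussed with the matrix/angiogenesis axis).
  Tagged `reconstructed`.

## Source tags

Vendor footnote symbols are stored opaquely in `source_tag`:
`*` Santa Cruz, `#` DAKO, `$` Neomarkers, `@` ZYMED, `&` Abcam, `!` NIH gift.
`reconstructed` marks rows introduced by the reconciliations above.
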