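# Deposited network files (not redistributed)

Two acceptance tests check the pipeline against the originally
deposited EGFR signalling network files, which are not shipped with
this repository.  To run them, download the study's supplementary
network spreadsheet and model exports and place them here as:

- `EGFR_SN.xlsx` (or `EGFR_SN.json` / an `EGFR_SN/` TSV directory) —
  the reconstructed signalling network workbook with sheets
  `Reactions`, `Species`, `GPRs`, `Modifiers`, `Inhibitors`,
  `Activators`;
- `EGFR_E.json` / `EGFR_M.json` — the epithelial and mesenchymal
  context models.

Without these files the two tests fail with a message pointing here;
all other tests are self-contained.
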