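#!/usr/bin/env Rscript
# Optional exporter: write the toxicokinetic parameter CSV consumed by
# `bbb-ivive predict` from the httk package (fraction unbound in blood and
# steady-state serum concentration at 1 mg/kg/day).
#
# Usage: Rscript scripts/export_httk.R compounds.csv out.csv
#   compounds.csv: columns compound_id, casrn
#
# Requires the httk package, which is not bundled; this script is a
# convenience only and nothing in the Python package depends on it.

suppressMessages({
  if (!requireNamespace("httk", quietly = TRUE)) {
    stop("the 'httk' package is not installed")
  }
  library(httk)
})

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 2) stop("usage: export_httk.R compounds.csv out.csv")

compounds <- read.csv(args[1], stringsAsFactors = FALSE)
rows <- lapply(seq_len(nrow(compounds)), function(i) {
  casrn <- compounds$casrn[i]
  fub <- tryCatch(
    suppressWarnings(get_fup(chem.cas = casrn)),
    error = function(e) NA_real_
  )
  css <- tryCatch(
    # µM at a constant 1 mg/kg/day oral dose
    suppressWarnings(calc_analytic_css(
      chem.cas = casrn, daily.dose = 1, output.units = "uM"
    )),
    error = function(e) NA_real_
  )
  data.frame(
    compound_id = compounds$compound_id[i],
    casrn = casrn,
    fub = fub,
    css_serum_uM = css,
    reference_dose_mg_kg_day = 1
  )
})
out <- do.call(rbind, rows)
write.csv(out, args[2], row.names = FALSE, na = "NA")
cat(sprintf("wrote %s (%d rows)\n", args[2], nrow(out)))
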