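# prenotrace compound / precursor preset registry
# version: 1
#
# Polyprenols (Pren-n): C(5n) H(8n+2) O, fully unsaturated alpha unit.
# Dolichols  (Dol-n):  C(5n) H(8n+4) O, alpha unit saturated (the reduction
# does not remove label-bearing positions; the unit still counts for N).
# Sterols: the triterpene skeleton is not an intact chain of C5 units, so
# n_units is a configurable maximum-label parameter (default 6, one per
# squalene-derived isoprene unit); carbon counts 28 (campesterol) and 29
# (stigmasterol, sitosterol).
registry_version: 1
precursors:
  DX:
    d: 2            # (5,5-2H2)-1-deoxy-D-xylulose, MEP pathway
    q: 0.029        # unlabeled-molecule fraction of the labeled substrate
    pathway: MEP
  MVL:
    d: 3            # ((6,6,6-2H3)methyl)mevalonolactone, MVA pathway
    q: 0.007
    pathway: MVA
compounds:
  Pren-9:  {family: polyprenol, n_units: 9,  formula: {C: 45,  H: 74,  O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Pren-10: {family: polyprenol, n_units: 10, formula: {C: 50,  H: 82,  O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Pren-11: {family: polyprenol, n_units: 11, formula: {C: 55,  H: 90,  O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Pren-12: {family: polyprenol, n_units: 12, formula: {C: 60,  H: 98,  O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-15:  {family: dolichol,   n_units: 15, formula: {C: 75,  H: 124, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-16:  {family: dolichol,   n_units: 16, formula: {C: 80,  H: 132, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-17:  {family: dolichol,   n_units: 17, formula: {C: 85,  H: 140, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-18:  {family: dolichol,   n_units: 18, formula: {C: 90,  H: 148, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-19:  {family: dolichol,   n_units: 19, formula: {C: 95,  H: 156, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-20:  {family: dolichol,   n_units: 20, formula: {C: 100, H: 164, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-21:  {family: dolichol,   n_units: 21, formula: {C: 105, H: 172, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-22:  {family: dolichol,   n_units: 22, formula: {C: 110, H: 180, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-23:  {family: dolichol,   n_units: 23, formula: {C: 115, H: 188, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  Dol-24:  {family: dolichol,   n_units: 24, formula: {C: 120, H: 196, O: 1}, adducts: ["[M+Na]+", "[M+K]+", "[M+NH4]+"]}
  campesterol:  {family: sterol, n_units: 6, formula: {C: 28, H: 48, O: 1}, adducts: ["M+"]}
  stigmasterol: {family: sterol, n_units: 6, formula: {C: 29, H: 48, O: 1}, adducts: ["M+"]}
  sitosterol:   {family: sterol, n_units: 6, formula: {C: 29, H: 50, O: 1}, adducts: ["M+"]}
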