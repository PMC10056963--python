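"""Physical constants shared by the qSIP estimator and the experiment simulator.

All density/molecular-weight conversions in this package flow through this
single table so that simulation and estimation are exactly inverse operations.

Constants follow the standard ``18O``-water qSIP calculation framework:

* DNA buoyant density (CsCl, g mL^-1) is linear in GC content.
* The molecular weight of an average nucleotide is linear in GC content and
  increases by a fixed amount when every exchangeable oxygen is ``18O``.
* Natural abundance of ``18O`` is subtracted so that unlabeled DNA has an
  excess atom fraction of exactly zero.
"""

#: Buoyant density (g mL^-1) of unlabeled DNA with GC = 0.
DENSITY_INTERCEPT = 1.646057

#: Increase in buoyant density (g mL^-1) per unit GC content.
DENSITY_SLOPE = 0.083506

#: Molecular weight (g mol^-1) of an average unlabeled nucleotide at GC = 0.
MW_INTERCEPT = 307.691

#: Increase in average-nucleotide molecular weight per unit GC content.
MW_GC_SLOPE = 0.496

#: Molecular-weight gain of an average nucleotide when fully 18O-labeled.
MW_MAX_18O_SHIFT = 12.07747

#: Natural abundance of 18O (atom fraction).
NATURAL_ABUNDANCE_18O = 0.002000429

#: Version tag written to run manifests; bump if any constant changes.
CONSTANTS_VERSION = "qsip-constants-1.0"
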