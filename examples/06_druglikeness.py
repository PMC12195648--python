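"""Lipinski / Veber / bioavailability-radar screening of a descriptor table.

Descriptors come from an upstream property predictor; the rules flag
compounds unlikely to be orally bioavailable.
"""

from fieldqsar import DescriptorRecord, rule_report

records = [
    DescriptorRecord("lead_1", mw=420.5, hbd=2, hba=7, clogp=3.1,
                     tpsa=95.0, nrb=6),
    DescriptorRecord("lead_2", mw=512.6, hbd=1, hba=8, clogp=4.2,
                     tpsa=110.0, nrb=8),
    DescriptorRecord("lead_3", mw=480.0, hbd=3, hba=9, clogp=5.8,
                     tpsa=150.0, nrb=11),
]
report = rule_report(records)
print(report.to_string(index=False))
# lead_1 is clean; lead_2 carries a single MW violation (still a classic
# Lipinski pass); lead_3 breaks both Veber thresholds and two Lipinski
# rules, so oral absorption is doubtful.
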