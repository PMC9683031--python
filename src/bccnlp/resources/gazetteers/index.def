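# member lexicons, one per majorType
diagnosis.lst
subtype.lst
prognostic.lst
excision_status.lst
measure_axis.lst
unit.lst
clock.lst
site.lst
laterality.lst
lesion.lst
specimen.lst
field_label.lst
department.lst
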