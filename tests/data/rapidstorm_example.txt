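# <localizations insequence="true" repetitions="variable"><field identifier="Position-0-0-0" syntax="floating point with . for decimals and optional scientific e-notation" semantic="position in sample space in X" unit="nanometer" min="0 m" max="2.0E-5 m" /><field identifier="Position-1-0-0" syntax="floating point with . for decimals and optional scientific e-notation" semantic="position in sample space in Y" unit="nanometer" min="0 m" max="2.0E-5 m" /><field identifier="ImageNumber-0-0" syntax="integer" semantic="frame number" unit="frame" min="0 fr" /><field identifier="Amplitude-0-0" syntax="floating point with . for decimals and optional scientific e-notation" semantic="emission strength" unit="A/D count" /><field identifier="PSFWidth-0-0" syntax="floating point with . for decimals and optional scientific e-notation" semantic="PSF FWHM in X" unit="nanometer" /></localizations>
100.0 200.0 0 5230.5 310.2
110.0 210.0 0 4100.8 295.7
500.0 500.0 1 7800.1 330.0
742.5 1288.0 1 2900.6 351.4
1503.2 330.6 2 6100.0 288.9
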