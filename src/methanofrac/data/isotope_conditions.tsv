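condition	analyte	timepoint	delta_permil	sigma_permil
R1	CO2	To	-35.1	0.3
R1	CO2	Tf	-29.0	0.3
R1	CH4	Tf	-55.9	0.3
R2	CO2	To	-34.6	0.3
R2	CO2	Tf	-28.2	0.3
R2	CH4	Tf	-55.9	0.3
R3	CO2	To	-35.2	0.3
R3	CO2	Tf	-28.4	0.3
R3	CH4	Tf	-55.8	0.3
R4	CO2	To	-35.9	0.3
R4	CO2	Tf	-33.3	0.3
R4	CH4	Tf	-75.7	0.3
R5	CO2	To	-35.7	0.3
R5	CO2	Tf	-31.8	0.3
R5	CH4	Tf	-74.2	0.3
R6	CO2	To	-35.8	0.3
R6	CO2	Tf	-32.0	0.3
R6	CH4	Tf	-72.5	0.3
B1	CO2	To	-26.1	0.8
B1	DIC	Tf	22.6	0.3
B1	CO2	Tf	18.9	0.3
B1	CH4	Tf	-32.9	0.3
B2	CO2	To	-26.1	0.8
B2	DIC	Tf	19.2	0.3
B2	CO2	Tf	15.5	0.3
B2	CH4	Tf	-34.2	0.3
B3	CO2	To	-26.7	0.3
B3	CO2	Tf	-22.8	0.3
B3	CH4	Tf	-99.4	0.3
B4	CO2	To	-26.7	0.3
B4	CO2	Tf	-23.0	0.3
B4	CH4	Tf	-99.4	0.3
B5	CO2	To	-25.5	0.3
B5	CO2	Tf	-24.4	0.3
B5	CH4	Tf	-91.2	0.3
B6	CO2	To	-25.5	0.3
B6	CO2	Tf	-21.6	0.3
B6	CH4	Tf	-89.0	0.3
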