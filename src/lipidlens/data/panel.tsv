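# Default 124-species choline-centric plasma panel.
# baseline_log2: log2 median control abundance (uM-like scale), set from
# class-typical plasma concentration ranges; per-species jitter is fixed.
species	lipid_class	baseline_log2
PC 24:0	PC	3.690
PC 26:0	PC	4.903
PC 28:0	PC	3.487
PC 28:1	PC	6.893
PC 30:0	PC	3.399
PC 30:1	PC	6.906
PC 30:2	PC	6.289
PC 32:0	PC	5.048
PC 32:1	PC	6.840
PC 32:2	PC	4.223
PC 32:3	PC	6.979
PC 33:0	PC	7.023
PC 33:1	PC	6.261
PC 33:2	PC	5.951
PC 34:0	PC	3.864
PC 34:1	PC	5.715
PC 34:2	PC	6.523
PC 34:3	PC	7.124
PC 34:4	PC	6.751
PC 35:0	PC	4.157
PC 35:1	PC	7.047
PC 36:0	PC	4.225
PC 36:1	PC	5.643
PC 36:2	PC	4.368
PC 36:3	PC	6.821
PC 36:4	PC	4.746
PC 36:5	PC	3.649
PC 36:6	PC	3.334
PC 37:0	PC	4.911
PC 38:0	PC	4.748
PC 38:1	PC	4.398
PC 38:2	PC	5.712
PC 38:3	PC	5.079
PC 38:4	PC	4.450
PC 38:5	PC	5.124
PC 38:6	PC	4.382
PC 40:0	PC	6.010
PC 40:1	PC	7.258
PC 40:2	PC	5.457
PC 40:3	PC	6.687
PC 40:4	PC	5.208
PC 40:5	PC	4.758
PC 40:6	PC	3.778
PC 42:0	PC	4.355
PC 42:1	PC	5.739
PC 42:2	PC	5.701
PC 42:4	PC	3.861
PC 42:5	PC	3.358
PC 42:6	PC	4.853
PC 44:0	PC	4.485
LPC 14:0	LPC	3.724
LPC 15:0	LPC	2.878
LPC 16:0	LPC	5.725
LPC 16:1	LPC	2.959
LPC 17:0	LPC	3.605
LPC 18:0	LPC	5.370
LPC 18:1	LPC	4.829
LPC 18:2	LPC	4.971
LPC 18:3	LPC	4.449
LPC 19:0	LPC	3.346
LPC 20:0	LPC	2.581
LPC 20:3	LPC	4.364
LPC 20:4	LPC	3.431
LPC 22:0	LPC	2.098
LPC 22:6	LPC	5.731
LPC 24:0	LPC	2.450
LPC 26:0	LPC	4.029
LPC 26:1	LPC	2.023
LPC 28:0	LPC	3.010
LPC 28:1	LPC	3.518
SM 18:1;O2/14:0	SM	5.239
SM 18:1;O2/15:0	SM	5.276
SM 18:1;O2/16:0	SM	2.601
SM 18:1;O2/16:1	SM	4.215
SM 18:1;O2/17:0	SM	5.287
SM 18:1;O2/18:0	SM	5.127
SM 18:1;O2/18:1	SM	3.339
SM 18:1;O2/20:0	SM	4.631
SM 18:1;O2/20:2	SM	4.196
SM 18:1;O2/21:0	SM	2.413
SM 18:1;O2/22:0	SM	3.261
SM 18:1;O2/22:1	SM	4.344
SM 18:1;O2/22:2;O	SM	4.008
SM 18:1;O2/23:0	SM	4.488
SM 18:1;O2/24:0	SM	3.228
SM 18:1;O2/24:1	SM	4.944
SM 18:1;O2/24:2	SM	2.211
SM 18:1;O2/25:0	SM	5.489
SM 18:1;O2/26:0	SM	3.642
SM 18:1;O2/26:1	SM	3.174
PC O-30:0	PC O-	-1.117
PC O-30:1	PC O-	-1.368
PC O-32:0	PC O-	1.865
PC O-32:1	PC O-	1.716
PC O-32:2	PC O-	1.669
PC O-34:0	PC O-	1.749
PC O-34:1	PC O-	-0.285
PC O-34:2	PC O-	-0.697
PC O-34:3	PC O-	-0.181
PC O-36:0	PC O-	-0.427
PC O-36:2	PC O-	-0.111
PC O-36:3	PC O-	2.423
PC O-36:4;2.0	PC O-	-0.401
PC O-36:5	PC O-	2.086
PC O-38:4	PC O-	1.466
PC O-38:5	PC O-	2.276
PC O-38:6	PC O-	0.395
PC O-40:1	PC O-	-1.129
PC O-40:6	PC O-	-1.092
CAR 2:0	CAR	-4.048
CAR 3:0	CAR	-4.004
CAR 4:0	CAR	-2.110
CAR 5:0	CAR	-3.935
CAR 6:0	CAR	-1.076
CAR 8:0	CAR	-1.338
CAR 10:0	CAR	-1.040
CAR 10:1	CAR	-2.536
CAR 12:0	CAR	-3.483
CAR 12:1	CAR	-2.974
CAR 14:0	CAR	-3.939
CAR 14:1	CAR	-1.215
CAR 14:2	CAR	-1.340
CAR 16:0	CAR	-2.280
CAR 18:1	CAR	-4.044
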