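outlier_weight	0.01
lrr_uniform	-6	3
baf_uniform	0	1
state	pi	mean_region_len	lrr_mean	lrr_sd	baf_g3_mean	baf_g3_sd
O	0.01578947368421053	5000000	-4	1	0.5	0.20000000000000001
F	0.01578947368421053	5000000	-0.66000000000000003	0.22	0	0.02
FF	0.01578947368421053	5000000	0	0.17999999999999999	0	0.02
FM	0.69999999999999996	100000000	0	0.17999999999999999	0.5	0.040000000000000001
FFF	0.01578947368421053	5000000	0.40000000000000002	0.20000000000000001	0	0.02
FFM	0.01578947368421053	5000000	0.40000000000000002	0.20000000000000001	0.33333333333333331	0.040000000000000001
FFFF	0.01578947368421053	5000000	0.68000000000000005	0.20999999999999999	0	0.02
FFFM	0.01578947368421053	5000000	0.68000000000000005	0.20999999999999999	0.25	0.040000000000000001
FFMM	0.01578947368421053	5000000	0.68000000000000005	0.20999999999999999	0.5	0.040000000000000001
FFFFF	0.01578947368421053	5000000	0.89000000000000001	0.23000000000000001	0	0.02
FFFFM	0.01578947368421053	5000000	0.89000000000000001	0.23000000000000001	0.20000000000000001	0.040000000000000001
FFFMM	0.01578947368421053	5000000	0.89000000000000001	0.23000000000000001	0.40000000000000002	0.040000000000000001
FFFFFF	0.01578947368421053	5000000	1.0600000000000001	0.23999999999999999	0	0.02
FFFFFM	0.01578947368421053	5000000	1.0600000000000001	0.23999999999999999	0.16666666666666666	0.040000000000000001
FFFFMM	0.01578947368421053	5000000	1.0600000000000001	0.23999999999999999	0.33333333333333331	0.040000000000000001
FFFMMM	0.01578947368421053	5000000	1.0600000000000001	0.23999999999999999	0.5	0.040000000000000001
FFFFFFF	0.01578947368421053	5000000	1.21	0.25	0	0.02
FFFFFFM	0.01578947368421053	5000000	1.21	0.25	0.14285714285714285	0.040000000000000001
FFFFFMM	0.01578947368421053	5000000	1.21	0.25	0.2857142857142857	0.040000000000000001
FFFFMMM	0.01578947368421053	5000000	1.21	0.25	0.42857142857142855	0.040000000000000001
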