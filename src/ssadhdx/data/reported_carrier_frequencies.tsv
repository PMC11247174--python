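population	carrier_den_base	prevalence_den_base	carrier_den_extended	prevalence_den_extended	fold_increase
pan_ethnic	376	564000	236	223000	2.4
african	519	1000000	139	77000	13.0
east_asian	411	677000	260	269000	2.5
south_asian	467	871000	261	271000	3.2
admixed_american	375	562000	237	225000	2.5
ashkenazi	2700	29500000	1724	11900000	2.5
remaining	308	377000	213	181000	2.1
european_non_finnish	359	515000	238	226000	2.3
european_finnish	2292	2100000	553	1200000	1.8
middle_eastern	428	732000	375	563000	1.3
amish			456	832000
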