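paradigm	indicator	state	mean	sd	lower	upper
gaze_stability	avg_blink_duration	fusion	0.317	0.771	-0.454	1.088
gaze_stability	avg_blink_duration	rivalry	-0.654	0.2	-0.854	-0.454
gaze_stability	avg_saccade_amplitude	fusion	0.525	0.769	-0.244	1.294
gaze_stability	avg_saccade_amplitude	rivalry	-1.082	0.389	-1.471	-0.693
gaze_stability	median_saccade_amplitude	fusion	0.527	0.759	-0.232	1.286
gaze_stability	median_saccade_amplitude	rivalry	-1.088	0.405	-1.493	-0.683
gaze_stability	sd_saccade_amplitude	fusion	0.381	0.784	-0.403	1.165
gaze_stability	sd_saccade_amplitude	rivalry	-0.785	0.382	-1.167	-0.403
straight_curve	avg_saccade_amplitude	fusion	-1.412	0.507	-1.919	-0.905
straight_curve	avg_saccade_amplitude	rivalry	0.397	1.302	-0.905	1.700
straight_curve	median_saccade_amplitude	fusion	-1.455	0.525	-1.980	-0.950
straight_curve	median_saccade_amplitude	rivalry	0.33	1.28	-0.950	1.610
straight_curve	sd_saccade_amplitude	fusion	-1.368	0.541	-1.909	-0.827
straight_curve	sd_saccade_amplitude	rivalry	0.359	1.186	-0.827	1.545
straight_curve	sac_avg_velocity	fusion	0.747	0.371	0.376	1.118
straight_curve	sac_avg_velocity	rivalry	-0.509	0.895	-1.404	0.376
straight_curve	sac_peak_velocity	fusion	-0.760	0.076	-0.836	-0.684
straight_curve	sac_peak_velocity	rivalry	0.816	1.492	-0.676	2.308
smooth_pursuit	avg_saccade_amplitude	fusion	1.421	0.813	0.608	2.234
smooth_pursuit	avg_saccade_amplitude	rivalry	-1	0.392	-1.392	0.608
smooth_pursuit	median_saccade_amplitude	fusion	0.507	0.855	-0.348	1.362
smooth_pursuit	median_saccade_amplitude	rivalry	-0.955	0.403	-1.358	-0.552
smooth_pursuit	sd_saccade_amplitude	fusion	0.527	0.971	-0.444	1.498
smooth_pursuit	sd_saccade_amplitude	rivalry	-0.82	0.376	-1.196	-0.444
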