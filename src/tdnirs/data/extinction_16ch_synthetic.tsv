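# Synthetic extinction table for the 16 spectral channels (680-867.5 nm,
# 12.5 nm spacing).  Values are an approximate rendition of published
# compilations of the molar absorption spectra of oxy- and deoxyhemoglobin
# and of the absorption spectrum of pure water, smoothed onto the channel
# centers; they reproduce the qualitative spectral features (Hb band near
# 760 nm, isosbestic crossing near 800 nm, water shoulder near 740 nm) and
# are intended for simulation and self-consistent testing, not for
# quantitative re-analysis of measured spectra.
# Columns: wavelength_nm  eps_hbo2_per_mM_cm  eps_hb_per_mM_cm  mua_water_per_cm
# eps_* are decadic molar absorption coefficients, 1/(mM cm);
# mua_water is the natural absorption coefficient of pure water, 1/cm.
680.0	0.2778	2.4080	0.0045
692.5	0.2800	2.0400	0.0050
705.0	0.2906	1.7000	0.0072
717.5	0.3232	1.3500	0.0100
730.0	0.3900	1.1250	0.0170
742.5	0.4527	1.2200	0.0270
755.0	0.5520	1.4500	0.0270
767.5	0.6230	1.4200	0.0255
780.0	0.7100	1.0754	0.0230
792.5	0.7680	0.8800	0.0215
805.0	0.8300	0.8100	0.0215
817.5	0.8900	0.7600	0.0250
830.0	0.9500	0.7100	0.0310
842.5	1.0150	0.6950	0.0400
855.0	1.0700	0.7000	0.0450
867.5	1.1250	0.7300	0.0500
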