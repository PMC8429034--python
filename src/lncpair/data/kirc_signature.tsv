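pair_id	coef	hr	hr_low	hr_high	p
AC016700.2|AC093001.1	-0.555606139437541	0.573724398796137	0.416297695146405	0.790683421050959	0.000686076662003585
AL355075.2|AC015845.2	0.430419065848712	1.53790187067958	1.01755489950781	2.32433863272024	0.0410972283642356
AL132989.1|AL117379.1	-0.492662779184755	0.610997275328431	0.42746865065855	0.87332175092522	0.00686828997559175
AL355803.1|AL355488.1	-0.337782984347439	0.713350079234553	0.515147153257942	0.987811603588818	0.0419716042136084
AC023509.3|AL031846.2	0.368641620152125	1.44576937621004	0.956818971469132	2.18458156821172	0.0800537100889237
AC067817.2|AD001527.1	-0.600072662204743	0.548771759679331	0.397286721159376	0.758017895344506	0.000271616905474768
AL031710.1|AL031846.2	-0.372132850780792	0.689262667357912	0.486341990519643	0.976849693989471	0.0364731879647768
AL031846.2|AL031670.1	-0.306752711799432	0.735832541115505	0.501459754200406	1.07974672748735	0.1169244327575
AL031846.2|AC012615.6	-0.450512101167986	0.637301705094545	0.390057679070148	1.04126513874727	0.0720924820494324
AL031670.1|AC025917.1	0.327629977864943	1.38767540666321	0.898479178435956	2.14322499672168	0.139602853715524
AC012615.6|AC020907.4	-0.37879660475502	0.684684860149524	0.474231274929152	0.988533195723983	0.0432267830019594
AL132989.1|AL031429.2	0.255953118485003	1.29169217003435	0.906761769946673	1.84002978227255	0.156248628062543
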