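logfc	t	p	df_total	s2post
-0.3350932351823498467	-0.7491739194028799176	0.467543724999088584	12.567865472192143	0.60018795494662514
-0.6010281945062053710	-2.2858805904514900575	0.040323719191359311	12.567865472192143	0.20739766642124827
-1.1029904940137160718	-2.3181893507283888312	0.038000306059896335	12.567865472192143	0.67915199524960013
 0.7998938106886687160	 1.4551260938009673573	0.170153511357404613	12.567865472192143	0.90653519588905151
 0.6886535261468396119	 3.2938390704630449157	0.006059240025136357	12.567865472192143	0.13113482845014793
-1.4528693276537820722	-1.9711751954468865744	0.071130565142415295	12.567865472192143	1.62976097436891654
-2.0132634905207922316	-2.8411658908342780627	0.014289097179489075	12.567865472192143	1.50636184282720786
 0.7388916468634934009	 1.2187638098037485435	0.245316834049175841	12.567865472192143	1.10266520149362957
 0.0177850798625365202	 0.0688864381015201893	0.946163947079862178	12.567865472192143	0.19997027111392515
 0.2883330533216883484	 0.7368073353075930143	0.474769917348465964	12.567865472192143	0.45941189429702151
 0.2847368029832731962	 0.6234100779848021912	0.544163467775484522	12.567865472192143	0.62583641025483849
-0.0756527833224316520	-0.1089279329383763817	0.914979576569540543	12.567865472192143	1.44708003378081806
 0.8162888962747806287	 1.7694348779822071105	0.101061595139518193	12.567865472192143	0.63846907351570237
 0.7433678195308840442	 0.9517616073998119708	0.359164131489851601	12.567865472192143	1.83008981335990728
-0.2437504033963895644	-0.6086360393979752814	0.553607621021782959	12.567865472192143	0.48116786077590273
-0.3072924409133441226	-0.6993601397283315535	0.497067265251795121	12.567865472192143	0.57919293706873609
 0.3010133602459504343	 0.8546881491271892672	0.408721144871073694	12.567865472192143	0.37211522037045552
 0.1634295869623663966	 0.7535781417783142810	0.464986804285268063	12.567865472192143	0.14109968207981155
-0.0154625435009750761	-0.0290933392419329556	0.977247058082923115	12.567865472192143	0.84741467678429294
-0.0061910174227416369	-0.0084977217276248507	0.993353286103421995	12.567865472192143	1.59235646907596440
 1.2357463577611709216	 2.6437331062180180474	0.020733396898657087	12.567865472192143	0.65545776660869326
 0.3353614897115512195	 0.8642694688717165175	0.403634134220551721	12.567865472192143	0.45169916964786122
-0.2665315032048029553	-0.3658742680519266877	0.720543451292279258	12.567865472192143	1.59204235946041628
-0.5727094661254723551	-0.6054936173132560162	0.555627962411026299	12.567865472192143	2.68392786165939912
-0.4312318007502515260	-1.0313543351853804442	0.321814556757711479	12.567865472192143	0.52447768841124676
 0.4155136717765103294	 1.7425504380348100231	0.105808241382014459	12.567865472192143	0.17057727637990086
-0.6552775101718038009	-1.0948064954384455483	0.294139636514165470	12.567865472192143	1.07472425264535021
 0.2637462158473048435	 1.3385230115740964774	0.204437388033911621	12.567865472192143	0.11647750127826247
-0.3061755843096038987	-1.2695436395131938223	0.227252252867457094	12.567865472192143	0.17448861578809763
 0.4592630552341300798	 0.7249366072133620609	0.481770768123676363	12.567865472192143	1.20404914628248694
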