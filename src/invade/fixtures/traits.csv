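species,gestation_len,group_size,body_mass,litter_size,latitude_range,home_range
sp001,0.03535292838,0.7297568471,0.3434226939,-0.2775064269,-0.2398071152,-0.9712334558
sp002,0.06610104166,0.7569302274,-1.499531732,-999,-0.4293702349,0.9189520603
sp003,1.696413031,-0.6009521568,-1.69268695,1.265414028,-0.8667136475,-999
sp004,0.9375567679,0.028943425,-0.06204157773,-0.456494304,1.495480505,1.007207995
sp005,-1.489779224,1.763066199,0.5470924356,-0.4794913611,1.519400436,-0.03184106313
sp006,-0.4056800962,-999,0.7936746376,-2.752242829,-1.692596162,-0.1539141744
sp007,-999,-999,-1.581467452,-0.5179730337,-999,-0.1184418744
sp008,0.2840062548,0.4407799837,-1.405346771,1.555369082,2.077013361,0.1834736433
sp009,-1.979512269,2.007212924,0.9122645155,0.3144094786,-999,0.09237139059
sp010,-0.64906264,0.7587685531,1.492256028,0.9633854316,-999,-0.6783248277
sp011,-0.8092971592,0.0435582296,-1.911513569,-0.5387140795,-1.326578376,-1.016621696
sp012,0.4656006688,0.5500472653,-0.2313639669,-999,-999,0.9519960668
sp013,-0.3167991742,0.4137878418,-2.016857871,-999,-0.3373090532,-1.194254685
sp014,-1.065853714,1.911985088,-0.7395952425,-2.348230534,-0.1857093944,1.47589038
sp015,0.956533029,1.608646948,-0.2989616018,1.540958065,-0.4445553681,-0.06615238893
sp016,-0.8293746071,0.309401401,1.6291498,0.7567236889,-0.8435553828,-999
sp017,-0.7149595347,0.4857418015,0.8070989326,-1.080998173,1.313634399,-1.055072207
sp018,-999,-999,0.04915378834,1.26909401,0.1112777348,-0.5689173045
sp019,-0.9700126233,-999,-0.5704522462,1.333438535,-999,-999
sp020,-0.999775389,-0.702326531,-0.2344112936,1.392873189,-0.3799973374,-0.3038983675
sp021,-1.132843754,-0.441278336,-0.2367355924,0.4850060157,-0.4956743116,-1.481801198
sp022,-999,-0.4137853444,-999,-999,1.380055097,-0.5483649017
sp023,-999,-0.08285103986,-0.4465827018,0.212860929,0.457505174,1.498546916
sp024,-0.5050840967,-1.862678773,0.8949294985,-0.148895147,2.205430951,1.080248672
sp025,-0.7836501707,1.190388428,-1.091615478,0.0592368422,-999,0.5772072144
sp026,-1.906350494,-999,0.4242785121,-999,0.4974885335,2.026080398
sp027,0.601652103,-0.9803839226,-0.09622387999,0.1580558841,1.594027115,-1.244474475
sp028,-0.9248168097,0.8771628664,0.683381657,-999,1.449326196,-1.275196536
sp029,1.80024747,-0.01853731674,0.8861025807,0.1527257957,-0.4724613215,-999
sp030,0.5201147799,-999,-0.9248073954,-999,-0.4401629677,-0.02619933392
sp031,0.1669116091,-1.267674668,2.665349922,2.051338628,0.2155501129,-0.01771090768
sp032,-0.4775585877,-1.206419661,0.7868796903,0.7992896164,0.3163816417,-999
sp033,-0.1356871785,-0.5680682501,-1.35435971,-0.4753507064,-999,-999
sp034,-0.3325838631,0.4653178615,-0.249791691,0.4510709736,-999,0.8390553997
sp035,-0.9308675727,-0.2742794198,0.4334466046,0.1550300411,-0.3745787391,-999
sp036,1.317407317,-0.1597751566,2.118938686,-0.8402134251,-0.09648936318,-999
sp037,0.380579583,-1.392051718,-0.1722256494,-0.1619158255,-999,-0.0788517363
sp038,1.779311678,-999,-999,-1.365453251,0.02322278291,-0.2532126564
sp039,1.584971533,-1.742349551,-1.026022421,-999,0.9855628248,-999
sp040,-999,-999,-1.059667931,-0.7243228958,-999,-0.3091431102
sp041,0.03188410324,1.39947473,1.118820921,0.0350200917,-0.3992743691,-1.077391002
sp042,-0.583295474,0.9771126347,0.6291940542,0.3773162981,0.618165724,-1.301193359
sp043,-0.07082174631,1.395103012,0.961132755,0.5212070154,-0.1411010612,-0.4623655799
sp044,-999,-999,-999,1.225756564,-999,1.453692507
sp045,-0.4244174598,0.09450799037,-1.968064906,0.2025553274,2.163311667,2.743449289
sp046,-2.001544856,0.7720137296,-0.9909394377,0.0009597977683,0.953768501,-0.8173230666
sp047,0.7412978622,0.6504890235,-1.911096947,-1.955079931,-0.6543340174,-999
sp048,0.8818545293,-1.765472918,-0.244510043,-0.3353142412,-999,0.5230791549
sp049,2.179000197,0.6445858858,1.585315202,-0.2521675875,0.2832618437,0.6869220431
sp050,0.4580660628,-1.083021484,0.6207275834,-0.3923809896,0.548754771,0.9396930936
sp051,-2.345930926,-999,-0.9763725057,0.150671021,-0.834474651,0.1108239306
sp052,0.4623504293,2.123508667,0.3681019604,-1.581664284,-999,0.07876680573
sp053,-0.9656583764,-0.1970349038,-1.063836941,-999,-1.046046799,1.408223619
sp054,-1.015339862,-1.040997688,-1.170587073,-1.098834964,-1.220650901,1.794907554
sp055,2.264467888,-999,-1.474727514,-0.8781217402,-0.5787015017,-999
sp056,-999,-999,-0.4015573166,0.9267747503,-2.554193388,-999
sp057,0.01596187576,-0.4850241664,-1.554507401,0.1268685042,-1.368149668,0.8450900432
sp058,0.04803744979,-1.180513046,0.5113513451,0.4574956232,0.4555455181,0.6467846435
sp059,-1.1932542,-0.5210785456,0.1685356467,2.940462532,1.83637398,-0.3525525368
sp060,0.9287577245,0.2752006317,0.3543803998,-0.3678955566,-0.2948814393,-0.3299684879
sp061,-0.9151811269,0.1074186569,1.435973155,-1.103732474,-0.8648287133,0.3831092152
sp062,-0.6471673008,-0.8142344777,0.978948937,-0.954766294,0.4955472457,-0.9403180717
sp063,-0.4917146136,0.5413837169,0.4861465225,-999,-0.4497429331,0.2003494947
sp064,-0.892270289,0.846204424,-999,-1.004991221,1.214697349,-0.979962939
sp065,0.5605627581,0.7823324506,-0.5787653184,1.258622996,-0.2991316744,1.427639082
sp066,-0.9806219305,0.4885376003,1.287428488,0.2786773488,-0.4851801351,0.1210151688
sp067,-0.8446045967,-1.717117495,-1.005579019,0.5566319674,-0.6844228569,-0.458832792
sp068,-1.881917211,0.02603823407,-1.050528966,-0.5918991593,-999,-0.4515490807
sp069,-0.1024777205,0.9973051184,-1.457152462,1.279263967,0.853741813,0.8504324911
sp070,-1.059242362,-1.210741937,0.004234748703,0.04727567188,0.632018487,-999
sp071,-0.1359098662,0.6398840903,0.6354029584,-0.05846055462,1.520534712,1.181748143
sp072,-999,1.314845253,-0.8126284429,0.231702972,2.593919547,-0.9398135581
sp073,0.5682733523,-999,-1.608082239,-999,0.5828546597,-999
sp074,0.2785975852,-0.03382535845,-999,-0.1043859793,1.324226078,-0.312639678
sp075,1.068699811,-999,0.1384831507,0.6304143103,-0.8467228085,-999
sp076,-999,0.5236745518,-0.5117112962,1.233262328,1.789831575,-0.1172495214
sp077,-999,0.6444810369,0.2445595109,-1.637775653,2.807700368,-1.097194475
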