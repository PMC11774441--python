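"sample","f0","f1","f2","f3","f4","f5"
"s00",4.06697619498751,-5.38866516124161,1.71830526599451,0.0736205726328114,-0.60462245462891,-2.1245441502995
"s01",-2.96925015968494,-5.74822623402217,1.84098897572737,-1.36465778504133,-2.61299052193903,0.181909250184796
"s02",1.86383010575224,-7.78718598637853,2.87835091411704,-0.959626379283428,-2.99198391594592,2.3154964096539
"s03",2.02399582725283,-4.62920334407505,2.19611267970613,0.144004998624915,-0.645361915747721,4.60591565838299
"s04",2.4921747543276,-4.69657261403547,2.79897094351363,-0.688042715704855,-2.61144704902783,3.00402959814995
"s05",0.980133376117071,-4.33427548467125,2.27388148867219,-0.0182541755100126,-1.51767401931993,-0.152221645311096
"s06",-1.06253171054105,-8.24758658465493,2.13318535790413,-2.02009561427026,-0.822602888302437,6.01583788159537
"s07",0.261829946441655,-3.05825825493511,3.43660331452851,0.0860988947912039,-1.77062914209221,1.69201051805799
"s08",-0.753761137508025,-3.47206534058638,2.76037614850892,-1.83872059888434,-1.51958921073663,4.90263053970123
"s09",1.88365320548569,-4.98164846442383,2.83258892900116,-1.31554221297501,-0.675237629197685,3.95221092061118
"s10",4.59929237846204,-7.10191323347675,3.02848682864751,-3.32503694596087,-2.60777252955748,-1.97247717169952
"s11",1.77382469494598,-3.51578871755749,4.53721529302133,0.16586372647863,-1.93233191291858,2.01827177790785
"s12",4.92956374913675,-6.53541245011665,4.10146703101556,1.78975389522569,-2.7965502154341,2.61242851268914
"s13",1.8704583347172,-9.88556087652323,1.68815851942207,-3.4544232621366,-1.54312560051161,2.86381582728635
"s14",2.61288338414605,-5.13789026620314,3.67220016557413,-0.773265413185579,-2.35329597274491,-2.3209469521687
"s15",2.56519543343319,-1.62622217910509,2.60605630491745,-1.31128134354472,-0.724121027524999,3.06580589168635
"s16",0.878338328542971,-6.85906657628515,1.7249706770099,-0.731867371295176,-1.25223071893007,0.820606520192633
"s17",1.29281734667518,-5.16845288895965,1.43765247335027,1.17928222549063,0.0015384272228629,3.71556627716113
"s18",-0.910003465803617,-1.72552993343898,2.20416146385501,-1.53431384138325,0.191204947306722,2.02758847830169
"s19",1.55230488192794,-3.46481124714386,4.03635155457834,-3.22250568872771,-1.21613012161449,1.09876145578575
"s20",5.67137836353368,-8.09618968286481,3.53143500018653,-1.35256422017049,0.964137157152782,4.27102014939513
"s21",2.88418462795547,-0.230269575909127,2.42669851944365,-0.349088892718545,0.164870511661495,4.36791806409275
"s22",1.68242772768698,-4.00616026017351,2.67313193276348,-3.29712274905628,-1.49515673144421,0.0290628386150455
"s23",1.34176791712752,-2.16808149724636,1.66754820720477,-0.0093282216743128,-1.91294852785682,5.61925317994957
"s24",3.11883649727073,-4.15285774355165,4.78116284894121,-1.20748778817336,-3.22672144881688,3.12894229891316
"s25",0.918949011806024,-3.86276325501069,1.81016415299082,0.397046313277723,-3.93755262194204,2.1302529067167
"s26",1.83076870465982,-6.75875721842813,2.37356545029735,-3.14537888641207,-0.797564570007122,3.88196224414454
"s27",0.867545537915565,-2.2020029935523,2.45753992030096,-2.51643641456528,-2.23716091267772,0.162902024056604
"s28",2.04419511000537,-6.39332075020922,2.86999562881053,0.0901355114158674,-1.68480322583953,5.42662181689512
"s29",5.07511825608071,-7.29799760622465,2.66938940754531,-0.429786393461126,-2.88362573045763,-1.28807697158932
"s30",3.67891315343963,-3.5433495088249,3.04226749977103,-0.535515575593376,0.0242752573856677,3.09277903064446
"s31",2.14130486816874,-5.50844234518066,3.30932553023411,-1.19232443180183,-1.49680173413542,-0.916387813211454
"s32",1.69621879809493,-7.41325319980542,1.8335984833758,0.726335669860585,-1.7909924921738,6.31848058582618
"s33",1.49290792208912,-7.68499987712609,1.63246565586489,-3.36343679458289,-0.325367889597756,1.22564612126665
"s34",-0.645852877337075,-2.08338723186742,2.59013353219859,1.80912681349078,-0.311681893901368,1.84859225302727
"s35",1.12032210964974,-7.73266238117636,2.26280208771385,1.71721572422874,-1.687736716107,-1.52094438625409
"s36",2.04529348828863,-1.02126297755168,1.77331833985552,-2.46543682045861,-0.037011219757962,2.72463521149438
"s37",2.42970755777019,-3.43299391198295,3.81130327635467,0.323801223587186,-1.02740104750737,4.43759984985692
"s38",4.04964792876183,-6.05347548577557,2.06548599317604,1.34501640813834,-2.4186605571597,6.07891912809313
"s39",-1.20050619730272,-7.7659490836692,3.42454744582467,-1.99776629682171,0.358029379444084,3.26556250056772
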