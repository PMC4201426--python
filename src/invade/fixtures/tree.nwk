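(((sp001:30.553571553655015,sp002:30.553571553655015):7.2467536047449475,((sp003:1.070964179309492,sp004:1.070964179309492):24.844444077871117,sp005:25.9154082571806):11.884916901219368):58.93557199571744,((((sp006:6.728192497211087,(sp007:4.958658672226355,(sp008:2.2813371593597314,sp009:2.2813371593597314):2.6773215128666235):1.769533824984731):2.004642560313866,(sp010:7.148855140919641,sp011:7.148855140919641):1.5839799166053126):1.5555879456793422,(sp012:1.672688993931,sp013:1.672688993931):8.615734009273291):60.27937285247877,((((sp014:10.34519334633936,sp015:10.34519334633936):11.838315679506616,(((sp016:3.3606968130968027,sp017:3.3606968130968027):5.156018942033234,sp018:8.516715755130036):12.662927481330476,sp019:21.179643236460517):1.0038657893854646):21.63060628647747,(((((sp020:15.094009391524335,((sp021:0.8870511525590284,sp022:0.8870511525590284):2.6825858198884993,sp023:3.5696369724475274):11.524372419076807):11.210122084677739,((((sp024:7.375034882780703,sp025:7.375034882780703):11.113743409550704,sp026:18.488778292331414):0.8144471623384155,sp027:19.303225454669825):4.9674314676070885,sp028:24.270656922276917):2.0334745539251657):6.680555247958845,sp029:32.984686724160916):1.1304380673743406,((sp030:19.243871643150296,sp031:19.243871643150296):10.128094962610525,(((sp032:3.49507155618527,sp033:3.49507155618527):7.575983757771683,((sp034:0.4884184176035694,sp035:0.4884184176035694):3.273029761021238,sp036:3.7614481786248075):7.309607135332145):14.238452861469689,sp037:25.30950817542664):4.062458430334177):4.743158185774443):2.1216042179215022,(sp038:34.47119511546639,(sp039:14.25463488919913,((sp040:1.1482452424915435,sp041:1.1482452424915435):3.8951412078644565,sp042:5.043386450356):9.211248438843132):20.216560226267255):1.7655338939903789):7.577386302866683):12.07212728241357,((sp043:40.08833059781525,(((sp044:5.220994056675111,sp045:5.220994056675111):8.55058146372302,(sp046:9.206481617308116,sp047:9.206481617308116):4.5650939030900135):11.389072606291412,sp048:25.16064812668954):14.927682471125712):3.1701658970077435,(((((sp049:21.999379732119667,sp050:21.999379732119667):3.0449238138661743,sp051:25.044303545985837):10.750499686215825,(((sp052:2.5411662146873697,sp053:2.5411662146873697):13.33905725881984,(sp054:11.746468686377977,sp055:11.746468686377977):4.133754787129227):8.045507178755214,(((sp056:1.3674530322486091,sp057:1.3674530322486091):4.461575485074555,sp058:5.829028517323164):15.055627667542549,((sp059:1.429316644130421,sp060:1.429316644130421):1.8657264672715963,(sp061:0.0,sp062:0.0):3.2950431114020176):17.5896130734637):3.0410744673967103):11.86907257993924):5.273371753950668,((sp063:32.96509172030219,((sp064:1.2918821771238913,sp065:1.2918821771238913):1.5028021396456868,sp066:2.794684316769578):30.170407403532618):3.288394308291103,sp067:36.253486028593294):4.8146889575590315):1.456407940766375,((((sp068:8.328097651066543,sp069:8.328097651066543):11.124891977092467,((sp070:1.3910568920654702,sp071:1.3910568920654702):8.696021185617319,(sp072:1.8945845621609498,sp073:1.8945845621609498):8.192493515521841):9.36591155047622):10.593489164501166,sp074:30.046478792660167):4.362251961695968,(sp075:14.127355780290202,(sp076:1.096567113104454,sp077:1.096567113104454):13.030788667185748):20.28137497406594):8.115852172562557):0.7339135679042913):12.627746099914024):14.681553260946085):26.1681012984343):3.264102845882596;
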